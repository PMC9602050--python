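"""Locus-level post-processing: clumping, novelty calls and overlap counts.

A locus is a window around a lead SNP — the smallest-p significant SNP not
already covered by a previously emitted locus.  Positions are 1-based and
intervals closed (inclusive endpoints) throughout, the standard GWAS
summary-statistic convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from shaher.sumstats import SummaryStats

__all__ = [
    "Locus",
    "clump",
    "novel_loci",
    "trait_count_profile",
    "overlap_matrix",
    "GENOME_WIDE_P",
    "LOCUS_WINDOW_BP",
]

#: genome-wide significance level for clumping
GENOME_WIDE_P = 5e-8
#: locus half-width: the region spans this far on either side of the lead SNP
LOCUS_WINDOW_BP = 500_000


@dataclass(frozen=True)
class Locus:
    """A clumped locus: lead SNP plus the window it covers."""

    rsid: str
    chrom: str
    pos: int
    start: int
    end: int
    p: float
    mlog10p: float

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


def clump(
    stats: SummaryStats,
    p_threshold: float = GENOME_WIDE_P,
    window_bp: int = LOCUS_WINDOW_BP,
) -> List[Locus]:
    """Greedy distance-based clumping of a summary-statistic table.

    Repeatedly takes the smallest-p SNP below ``p_threshold`` not yet
    covered, emits a locus spanning ``window_bp`` either side of it
    (clipped at position 1), and removes all SNPs within that distance on
    the same chromosome.  Significance is evaluated in -log10 space so
    underflowed p-values clump correctly.  Ties on p break by (chr, pos)
    ascending; output is ordered by (chr, lead pos).
    """
    if p_threshold <= 0.0 or window_bp < 0:
        raise ValueError("p_threshold must be positive and window_bp nonnegative")
    mlp_cut = -np.log10(p_threshold)
    df = stats.df
    sig = df[df["mlog10p"] > mlp_cut]
    sig = sig.sort_values(
        ["mlog10p", "chr", "pos"], ascending=[False, True, True], kind="mergesort"
    )
    loci: List[Locus] = []
    covered: Dict[str, List[int]] = {}
    for row in sig.itertuples(index=False):
        leads = covered.get(row.chr, [])
        if any(abs(row.pos - lead) <= window_bp for lead in leads):
            continue
        leads.append(row.pos)
        covered[row.chr] = leads
        loci.append(
            Locus(
                rsid=row.rsid,
                chrom=row.chr,
                pos=int(row.pos),
                start=max(1, int(row.pos) - window_bp),
                end=int(row.pos) + window_bp,
                p=float(row.p),
                mlog10p=float(row.mlog10p),
            )
        )
    return sorted(loci, key=lambda l: (l.chrom, l.pos))


def novel_loci(
    target: Sequence[Locus], originals: Sequence[Sequence[Locus]]
) -> List[Locus]:
    """Target loci whose lead falls outside every original-trait locus span."""
    out = []
    for locus in target:
        hit = any(
            orig.contains(locus.chrom, locus.pos)
            for loci in originals
            for orig in loci
        )
        if not hit:
            out.append(locus)
    return out


def trait_count_profile(
    loci: Sequence[Locus],
    original_stats: Sequence[SummaryStats],
    per_trait_p: float = 1e-5,
) -> pd.DataFrame:
    """Per-locus count of original traits associated within the locus span.

    A trait counts as associated when its minimum p inside [start, end] is
    below ``per_trait_p`` (evaluated in -log10 space).  The locus lead
    -log10 p is carried along for boxplot-style summaries against the count.
    """
    mlp_cut = -np.log10(per_trait_p)
    rows = []
    for locus in loci:
        count = 0
        for stats in original_stats:
            df = stats.df
            inside = (
                (df["chr"] == locus.chrom)
                & (df["pos"] >= locus.start)
                & (df["pos"] <= locus.end)
            )
            if inside.any() and df.loc[inside, "mlog10p"].max() > mlp_cut:
                count += 1
        rows.append(
            {
                "rsid": locus.rsid,
                "chr": locus.chrom,
                "pos": locus.pos,
                "n_assoc_traits": count,
                "lead_mlog10p": locus.mlog10p,
            }
        )
    return pd.DataFrame(
        rows, columns=["rsid", "chr", "pos", "n_assoc_traits", "lead_mlog10p"]
    )


def overlap_matrix(
    loci_lists: Dict[str, Sequence[Locus]]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and min-scaled fractions of overlapping loci between traits.

    Entry (a, b) counts loci of a whose lead lies within any locus span of
    b; the scaled entry divides by min(|a|, |b|) (0 when either list is
    empty).  Diagonals hold the list sizes / 1.  The count matrix is not
    symmetric in general (lead-of-a-in-span-of-b differs from the reverse).
    """
    names = list(loci_lists)
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    scaled = pd.DataFrame(0.0, index=names, columns=names)
    for a in names:
        for b in names:
            la, lb = loci_lists[a], loci_lists[b]
            if a == b:
                counts.loc[a, b] = len(la)
                scaled.loc[a, b] = 1.0 if la else 0.0
                continue
            hit = sum(
                1
                for locus in la
                if any(other.contains(locus.chrom, locus.pos) for other in lb)
            )
            counts.loc[a, b] = hit
            denom = min(len(la), len(lb))
            scaled.loc[a, b] = hit / denom if denom else 0.0
    return counts, scaled
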