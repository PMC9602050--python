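"""sumCOT: GWAS summary statistics of linear combinations of traits.

Given harmonized per-trait Z-scores, allele frequencies and sample sizes,
the stage produces summary statistics of any linear combination k^T y of
the standardized traits.  Per SNP j the standardized-scale effect of trait
i is b_ij = z_ij * se_ij with se_ij = 1 / sqrt(N_ij); the combined effect
and its error variance follow from variance-covariance arithmetic,

    b_tj    = sum_i k_i b_ij / sqrt(k^T R k)
    se_tj^2 = sum_il k_i k_l R_il se_ij se_lj / (k^T R k)

where R is the phenotypic correlation matrix between the traits.  R doubles
as the correlation of the per-SNP effect-estimate errors across GWASs: when
estimated from insignificant Z-statistics it already absorbs partial sample
overlap, and under full overlap it equals the true phenotypic correlation.
The standardization by sqrt(k^T R k) gives the combined trait unit
phenotypic variance and cancels in z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from shaher.core import CorrelationMatrix, DegenerateCombinationError, TraitPanel
from shaher.maxsh import MaxshReport, run_maxsh
from shaher.screen import DEFAULT_SGI_THRESHOLD
from shaher.sumstats import SummaryStats, zscore_to_mlog10p, zscore_to_p

__all__ = [
    "harmonize",
    "combine",
    "effective_n",
    "estimate_pheno_corr",
    "pheno_corr_matrix",
    "gc_correct",
    "run_shaher",
    "ShaherResult",
]

logger = logging.getLogger(__name__)

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def harmonize(stats: Sequence[SummaryStats]) -> List[SummaryStats]:
    """Align >= 2 summary-statistic tables on shared variants and alleles.

    Variants are inner-joined on rsid; each table's Z/beta signs are flipped
    where its effect/other alleles are swapped relative to the first table;
    variants with inconsistent allele pairs or strand-ambiguous alleles
    (A/T, C/G) are dropped with logged counts.  Output order is
    deterministic (chr, pos).
    """
    if len(stats) < 2:
        raise ValueError("harmonize needs at least two tables")
    base = stats[0].sorted()
    bdf = base.df.set_index("rsid")
    ambiguous = {
        rsid
        for rsid, ea, oa in zip(bdf.index, bdf["ea"], bdf["oa"])
        if (str(ea).upper(), str(oa).upper()) in _AMBIGUOUS
    }
    if ambiguous:
        logger.info("harmonize: dropping %d strand-ambiguous variant(s)", len(ambiguous))
    shared = set(bdf.index) - ambiguous
    flips: List[pd.Series] = []
    for other in stats[1:]:
        odf = other.df.set_index("rsid")
        common = shared & set(odf.index)
        odf = odf.loc[sorted(common)]
        ref = bdf.loc[odf.index]
        same = (odf["ea"] == ref["ea"]) & (odf["oa"] == ref["oa"])
        swapped = (odf["ea"] == ref["oa"]) & (odf["oa"] == ref["ea"])
        bad = ~(same | swapped)
        if bad.any():
            logger.info(
                "harmonize: dropping %d variant(s) with inconsistent alleles "
                "between %s and %s", int(bad.sum()), base.trait, other.trait,
            )
        shared = common - set(odf.index[bad])
        flips.append(swapped)
    if not shared:
        raise ValueError("no variants shared by all tables after harmonization")

    keep = sorted(shared)
    out = []
    ref = bdf.loc[keep]
    for i, table in enumerate(stats):
        df = table.df.set_index("rsid").loc[keep]
        if i > 0:
            flip = flips[i - 1].reindex(keep).fillna(False).astype(bool)
            df.loc[flip, ["beta", "z"]] *= -1.0
            df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
            df.loc[flip, ["ea", "oa"]] = ref.loc[flip, ["ea", "oa"]].to_numpy()
        out.append(
            SummaryStats(
                df=df.reset_index(), trait=table.trait, effective_n=table.effective_n
            ).sorted()
        )
    return out


def _check_aligned(stats: Sequence[SummaryStats]) -> None:
    ids = stats[0].df["rsid"]
    for other in stats[1:]:
        if len(other.df) != len(ids) or not (other.df["rsid"] == ids).all():
            raise ValueError("tables are not harmonized (variant sets differ); "
                             "run harmonize() first")


def combine(
    stats: Sequence[SummaryStats],
    coeffs: Sequence[float],
    uphen: CorrelationMatrix,
    trait: str = "combined",
    var_tol: float = 1e-10,
) -> SummaryStats:
    """Summary statistics of the combination k^T y from harmonized inputs.

    The output beta/se are re-expressed on the per-allele dosage scale
    using the first table's allele frequencies; per-SNP N is the harmonized
    minimum across traits (a trait-level effective N is assigned separately
    by :func:`effective_n`).
    """
    k = np.asarray(coeffs, dtype=float)
    if len(stats) != k.shape[0] or uphen.k != k.shape[0]:
        raise ValueError("number of tables, coefficients and matrix dimension disagree")
    _check_aligned(stats)
    r = uphen.values
    var_c = float(k @ r @ k)
    if var_c <= var_tol:
        raise DegenerateCombinationError(
            f"combination has near-zero phenotypic variance ({var_c:.3e})"
        )
    z = np.column_stack([t.df["z"].to_numpy() for t in stats])  # m x K
    n = np.column_stack([t.df["n"].to_numpy() for t in stats])
    se_std = 1.0 / np.sqrt(n)
    b = z * se_std
    num = b @ k
    e = se_std * k  # m x K, k_i se_ij
    se2 = np.einsum("mi,il,ml->m", e, r, e)
    b_t = num / np.sqrt(var_c)
    se_t = np.sqrt(se2 / var_c)
    z_t = num / np.sqrt(se2)

    base = stats[0].df
    het = np.clip(2.0 * base["eaf"].to_numpy() * (1.0 - base["eaf"].to_numpy()), 1e-12, None)
    scale = np.sqrt(het)
    df = pd.DataFrame(
        {
            "rsid": base["rsid"],
            "chr": base["chr"],
            "pos": base["pos"],
            "ea": base["ea"],
            "oa": base["oa"],
            "eaf": base["eaf"],
            "beta": b_t / scale,
            "se": se_t / scale,
            "z": z_t,
            "p": zscore_to_p(z_t),
            "n": n.min(axis=1),
            "mlog10p": zscore_to_mlog10p(z_t),
        }
    )
    return SummaryStats(df=df, trait=trait).sorted()


def effective_n(combined: SummaryStats) -> float:
    """Median-based effective sample size of a combined trait.

    Inverts the SE-N relation per SNP, n_j = 1 / (2 p_j (1 - p_j) se_j^2)
    with se on the per-allele dosage scale, and returns the median over
    SNPs.  For an identity combination this recovers the input sample size
    exactly.
    """
    df = combined.df
    if df["eaf"].isna().any():
        raise ValueError("effective N requires an allele frequency for every SNP")
    het = 2.0 * df["eaf"].to_numpy() * (1.0 - df["eaf"].to_numpy())
    valid = (het > 0) & np.isfinite(df["se"]) & (df["se"] > 0)
    if not valid.any():
        raise ValueError("no SNP with usable EAF/SE for effective N")
    n_snp = 1.0 / (het[valid] * df["se"].to_numpy()[valid] ** 2)
    return float(np.median(n_snp))


def _prune_by_distance(df: pd.DataFrame, window_bp: int) -> np.ndarray:
    """Greedy positional pruning: keep one SNP per window along each chromosome."""
    keep = np.zeros(len(df), dtype=bool)
    for _, sub in df.groupby("chr", sort=True):
        last = None
        for idx, pos in zip(sub.index, sub["pos"]):
            if last is None or pos - last >= window_bp:
                keep[idx] = True
                last = pos
    return keep


def estimate_pheno_corr(
    stats_a: SummaryStats,
    stats_b: SummaryStats,
    z_max: float = 2.0,
    prune_window_bp: int = 500_000,
    min_snps: int = 100,
) -> float:
    """Phenotypic correlation between two traits from insignificant Z-scores.

    Independent SNPs are obtained by greedy distance pruning (one SNP per
    ``prune_window_bp``); SNPs with |z| < ``z_max`` in both traits then
    carry essentially no genetic signal, and the Pearson correlation of
    their Z-scores estimates the phenotypic correlation scaled by sample
    overlap.
    """
    a, b = harmonize([stats_a, stats_b])
    keep = _prune_by_distance(a.df, prune_window_bp)
    za = a.df.loc[keep, "z"].to_numpy()
    zb = b.df.loc[keep, "z"].to_numpy()
    null = (np.abs(za) < z_max) & (np.abs(zb) < z_max)
    if null.sum() < min_snps:
        raise ValueError(
            f"only {int(null.sum())} insignificant independent SNPs "
            f"(need >= {min_snps}) — estimate would be unstable"
        )
    return float(np.corrcoef(za[null], zb[null])[0, 1])


def pheno_corr_matrix(
    stats: Sequence[SummaryStats],
    z_max: float = 2.0,
    prune_window_bp: int = 500_000,
) -> CorrelationMatrix:
    """Pairwise phenotypic correlation matrix assembled from Z-scores."""
    k = len(stats)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r[i, j] = r[j, i] = estimate_pheno_corr(
                stats[i], stats[j], z_max=z_max, prune_window_bp=prune_window_bp
            )
    return CorrelationMatrix(np.clip(r, -1.0, 1.0))


def gc_correct(stats: SummaryStats, intercept: float) -> SummaryStats:
    """Genomic-control correction by an LD-score-regression intercept.

    When the intercept exceeds 1, standard errors are multiplied by its
    square root, Z-scores divided by it, and p-values recomputed; an
    intercept at or below 1 leaves the table unchanged.
    """
    if intercept <= 0.0:
        raise ValueError("intercept must be positive")
    if intercept <= 1.0:
        return stats
    factor = float(np.sqrt(intercept))
    df = stats.df.copy()
    df["se"] = df["se"] * factor
    df["z"] = df["z"] / factor
    df["p"] = zscore_to_p(df["z"].to_numpy())
    df["mlog10p"] = zscore_to_mlog10p(df["z"].to_numpy())
    return replace(stats, df=df)


@dataclass(frozen=True)
class ShaherResult:
    """Full-pipeline output: MaxSH report plus SGIT/UGIT summary statistics."""

    report: MaxshReport
    sgit: SummaryStats
    ugits: Tuple[SummaryStats, ...]

    @property
    def all_stats(self) -> Tuple[SummaryStats, ...]:
        return (self.sgit, *self.ugits)


def run_shaher(
    panel: TraitPanel,
    stats: Sequence[SummaryStats],
    threshold: float = DEFAULT_SGI_THRESHOLD,
    gc_intercepts: Optional[Dict[str, float]] = None,
) -> ShaherResult:
    """Run the full framework: screen, MaxSH, and sumCOT for SGIT and UGITs.

    ``gc_intercepts`` optionally maps output trait names ("SGIT",
    "UGIT_<trait>") to LD-score-regression intercepts for genomic-control
    correction of the combined statistics.
    """
    if len(stats) != panel.k:
        raise ValueError("one summary-statistic table per trait is required")
    report = run_maxsh(panel, threshold=threshold)
    aligned = harmonize(stats)
    gc_intercepts = gc_intercepts or {}

    def build(coeffs: np.ndarray, name: str) -> SummaryStats:
        out = combine(aligned, coeffs, panel.uphen, trait=name)
        out = replace(out, effective_n=effective_n(out))
        if name in gc_intercepts:
            out = gc_correct(out, gc_intercepts[name])
        return out

    sgit = build(report.weights.alpha, "SGIT")
    ugits = tuple(
        build(report.weights.gamma[:, i], f"UGIT_{panel.names[i]}")
        for i in range(panel.k)
    )
    return ShaherResult(report=report, sgit=sgit, ugits=ugits)
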