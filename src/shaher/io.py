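"""Readers and writers for summary statistics, matrices and configuration.

All formats are tab-delimited text.  Summary-statistic input tolerates the
common column-name dialects (SNP/rsid, A1/ea, FRQ/eaf, ...) unless strict
mode is on; matrices and heritability vectors carry trait labels that are
checked for consistency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from shaher.core import CorrelationMatrix, TraitPanel
from shaher.sumstats import COLUMNS, SummaryStats, zscore_to_mlog10p, zscore_to_p

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "read_matrix",
    "write_matrix",
    "read_h2",
    "write_h2",
    "read_panel",
    "DEFAULT_MAF_FILTER",
]

logger = logging.getLogger(__name__)

#: minor-allele-frequency filter applied on input
DEFAULT_MAF_FILTER = 0.01

# canonical name -> accepted synonyms (matched case-insensitively)
_SYNONYMS = {
    "rsid": ["rsid", "snp", "rs", "markername", "variant_id", "id"],
    "chr": ["chr", "chrom", "chromosome"],
    "pos": ["pos", "bp", "position", "base_pair_location"],
    "ea": ["ea", "a1", "effect_allele", "allele1"],
    "oa": ["oa", "a2", "other_allele", "allele2", "nea", "ref"],
    "eaf": ["eaf", "frq", "freq", "af", "effect_allele_frequency", "maf"],
    "beta": ["beta", "b", "effect", "effect_size"],
    "se": ["se", "stderr", "standard_error"],
    "z": ["z", "zscore", "z_score", "stat"],
    "p": ["p", "pval", "p_value", "pvalue"],
    "n": ["n", "nmiss", "n_samples", "samplesize", "n_total"],
    "mlog10p": ["mlog10p", "log10p", "neg_log10_p"],
}


def _map_columns(columns: Sequence[str], strict: bool) -> dict:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        for canonical, names in _SYNONYMS.items():
            accepted = [canonical] if strict else names
            if key in accepted and canonical not in mapping.values():
                mapping[col] = canonical
                break
    return mapping


def read_sumstats(
    path,
    maf_filter: float = DEFAULT_MAF_FILTER,
    strict: bool = False,
    trait: Optional[str] = None,
    bad_row_tolerance: float = 0.001,
) -> SummaryStats:
    """Read a tab-delimited summary-statistic file into canonical form.

    Requires rsid/chr/pos/ea/oa/eaf plus (z and n) or (beta and se and n);
    z is derived from beta/se when absent and vice versa.  Rows failing the
    MAF filter, rows with p exactly 0 (an underflowed, unusable value) and
    duplicate variant ids (first kept) are dropped with logged counts.
    Unparseable rows beyond ``bad_row_tolerance`` of the file are a hard
    error.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    mapping = _map_columns(raw.columns, strict)
    df = raw.rename(columns=mapping)
    required = ["rsid", "chr", "pos", "ea", "oa", "eaf"]
    missing = [c for c in required if c not in df.columns]
    has_z = "z" in df.columns and "n" in df.columns
    has_beta = "beta" in df.columns and "se" in df.columns and "n" in df.columns
    if missing or not (has_z or has_beta):
        raise ValueError(
            f"{path.name}: missing required columns {missing or '(z,n) or (beta,se,n)'}"
        )

    numeric = [c for c in ("pos", "eaf", "beta", "se", "z", "p", "n", "mlog10p")
               if c in df.columns]
    parsed = df.copy()
    for col in numeric:
        parsed[col] = pd.to_numeric(df[col], errors="coerce")
    must_parse = ["pos", "eaf", "n"] + (["z"] if has_z else ["beta", "se"])
    bad = parsed[must_parse].isna().any(axis=1)
    if bad.mean() > bad_row_tolerance:
        raise ValueError(
            f"{path.name}: {int(bad.sum())} unparseable rows exceed the "
            f"{bad_row_tolerance:.1%} tolerance"
        )
    if bad.any():
        logger.info("%s: dropped %d unparseable row(s)", path.name, int(bad.sum()))
    parsed = parsed[~bad]

    if "z" not in parsed.columns:
        parsed["z"] = parsed["beta"] / parsed["se"]
    if "se" not in parsed.columns or parsed["se"].isna().all():
        het = np.clip(2.0 * parsed["eaf"] * (1.0 - parsed["eaf"]), 1e-12, None)
        parsed["se"] = 1.0 / np.sqrt(het * parsed["n"])
    if "beta" not in parsed.columns or parsed["beta"].isna().all():
        parsed["beta"] = parsed["z"] * parsed["se"]
    if "p" not in parsed.columns:
        parsed["p"] = zscore_to_p(parsed["z"].to_numpy())
    if "mlog10p" not in parsed.columns:
        parsed["mlog10p"] = zscore_to_mlog10p(parsed["z"].to_numpy())

    n0 = len(parsed)
    maf = np.minimum(parsed["eaf"], 1.0 - parsed["eaf"])
    parsed = parsed[maf >= maf_filter]
    if len(parsed) < n0:
        logger.info("%s: dropped %d row(s) below MAF %g", path.name, n0 - len(parsed), maf_filter)

    n1 = len(parsed)
    parsed = parsed[parsed["p"] != 0.0]
    if len(parsed) < n1:
        logger.info("%s: dropped %d row(s) with p == 0", path.name, n1 - len(parsed))

    n2 = len(parsed)
    parsed = parsed.drop_duplicates(subset="rsid", keep="first")
    if len(parsed) < n2:
        logger.info("%s: dropped %d duplicate variant id(s)", path.name, n2 - len(parsed))

    parsed["pos"] = parsed["pos"].astype(np.int64)
    parsed["chr"] = parsed["chr"].astype(str)
    parsed["n"] = parsed["n"].astype(float)
    out = SummaryStats(
        df=parsed[COLUMNS].reset_index(drop=True),
        trait=trait if trait is not None else path.stem,
    ).sorted()
    return out


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write canonical tab-delimited output with round-trip float precision."""
    df = stats.df.copy()
    for col in ("eaf", "beta", "se", "z", "p", "mlog10p"):
        df[col] = [repr(float(v)) for v in df[col]]
    df["n"] = [repr(float(v)) for v in df["n"]]
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> Tuple[List[str], np.ndarray]:
    """Read a labeled square matrix (header row of trait names, row labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    names = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != names:
        raise ValueError(f"{path}: row labels do not match column labels")
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    return names, values


def write_matrix(names: Sequence[str], values: np.ndarray, path) -> None:
    # repr gives the shortest decimal that round-trips the double exactly
    df = pd.DataFrame(values, index=list(names), columns=list(names))
    df.map(lambda v: repr(float(v))).to_csv(path, sep="\t")


def read_h2(path) -> Tuple[List[str], np.ndarray]:
    """Read a heritability vector: header row of trait names, one value row."""
    df = pd.read_csv(path, sep="\t")
    if len(df) != 1:
        raise ValueError(f"{path}: expected exactly one row of heritabilities")
    return [str(c) for c in df.columns], df.iloc[0].to_numpy(dtype=float)


def write_h2(names: Sequence[str], h2: np.ndarray, path) -> None:
    row = [repr(float(v)) for v in np.asarray(h2, dtype=float)]
    pd.DataFrame([row], columns=list(names)).to_csv(path, sep="\t", index=False)


def read_panel(ugen_path, uphen_path, h2_path) -> TraitPanel:
    """Assemble a TraitPanel from matrix and heritability files, checking labels."""
    names_g, ugen = read_matrix(ugen_path)
    names_p, uphen = read_matrix(uphen_path)
    names_h, h2 = read_h2(h2_path)
    if names_g != names_p or names_g != names_h:
        raise ValueError("trait labels differ between input files")
    return TraitPanel(
        names=tuple(names_g),
        h2=h2,
        ugen=CorrelationMatrix(ugen),
        uphen=CorrelationMatrix(uphen),
    )
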