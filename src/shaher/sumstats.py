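"""In-memory container for per-SNP GWAS summary statistics of one trait.

A thin wrapper around a pandas DataFrame with a fixed column schema:

    rsid chr pos ea oa eaf beta se z p n mlog10p

``beta``/``se`` are on the per-allele dosage scale with the trait
standardized; ``z = beta / se``; ``mlog10p`` is -log10 of the two-sided
normal p-value, kept alongside ``p`` so extreme associations survive
floating-point underflow of ``p`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["SummaryStats", "COLUMNS", "zscore_to_p", "zscore_to_mlog10p"]

COLUMNS = ["rsid", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "z", "p", "n", "mlog10p"]

_LN10 = np.log(10.0)


def zscore_to_p(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value (underflows to 0 for |z| beyond ~38)."""
    return 2.0 * sps.norm.sf(np.abs(z))


def zscore_to_mlog10p(z: np.ndarray) -> np.ndarray:
    """-log10 of the two-sided normal p-value, computed in log space."""
    return -(sps.norm.logsf(np.abs(z)) + np.log(2.0)) / _LN10


@dataclass(frozen=True)
class SummaryStats:
    """GWAS summary statistics for one (possibly combined) trait."""

    df: pd.DataFrame
    trait: str = "trait"
    effective_n: Optional[float] = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        df = self.df.loc[:, COLUMNS].reset_index(drop=True)
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_arrays(
        cls,
        rsid,
        chrom,
        pos,
        ea,
        oa,
        eaf,
        z,
        n,
        beta=None,
        se=None,
        trait: str = "trait",
    ) -> "SummaryStats":
        """Build a table from aligned arrays, deriving beta/se when absent.

        When beta/se are not supplied they are reconstructed on the
        per-allele dosage scale from z, n and the allele frequency via
        se = 1 / sqrt(2 p (1 - p) n), beta = z * se.
        """
        z = np.asarray(z, dtype=float)
        n = np.asarray(n, dtype=float)
        eaf = np.asarray(eaf, dtype=float)
        if se is None:
            het = np.clip(2.0 * eaf * (1.0 - eaf), 1e-12, None)
            se = 1.0 / np.sqrt(het * n)
        se = np.asarray(se, dtype=float)
        beta = z * se if beta is None else np.asarray(beta, dtype=float)
        df = pd.DataFrame(
            {
                "rsid": np.asarray(rsid, dtype=str),
                "chr": np.asarray(chrom, dtype=str),
                "pos": np.asarray(pos, dtype=np.int64),
                "ea": np.asarray(ea, dtype=str),
                "oa": np.asarray(oa, dtype=str),
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "z": z,
                "p": zscore_to_p(z),
                "n": n,
                "mlog10p": zscore_to_mlog10p(z),
            }
        )
        return cls(df=df, trait=trait).sorted()

    def sorted(self) -> "SummaryStats":
        """Deterministic (chr, pos) order."""
        df = self.df.sort_values(["chr", "pos"], kind="mergesort").reset_index(drop=True)
        return replace(self, df=df)

    def validate(self) -> None:
        """Check internal consistency: z = beta/se, p matches z, positions unique.

        Raises ``ValueError`` on the first violated invariant.
        """
        df = self.df
        ok = np.isfinite(df["se"]) & (df["se"] > 0)
        if not ok.all():
            raise ValueError("nonpositive or non-finite standard errors")
        if not np.allclose(df["beta"] / df["se"], df["z"], atol=1e-8, rtol=1e-6):
            raise ValueError("z and beta/se disagree beyond tolerance")
        expected_p = zscore_to_p(df["z"].to_numpy())
        mask = expected_p > 0
        if not np.allclose(df.loc[mask, "p"], expected_p[mask], atol=1e-10, rtol=1e-8):
            raise ValueError("p does not match the two-sided normal tail of z")
        grouped = df.groupby("chr", sort=False)["pos"]
        if (grouped.diff().dropna() <= 0).any():
            raise ValueError("positions are not strictly increasing within chromosome")
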