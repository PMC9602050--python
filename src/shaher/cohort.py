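"""Individual-level cohort simulator for end-to-end testing of the framework.

Traits are generated from the two-component polygenic model: M0 "shared"
SNPs carry a single effect vector beta_0 scaled per trait by w_i h_i, and
M1 "unshared" SNPs carry per-trait effect vectors whose cross-trait
correlation follows U_unsh, scaled by sqrt(1 - w_i^2) h_i; the residual
noise is jointly normal with correlation U_env.  With standardized
genotypes and the 1/sqrt(M) effect scaling, the expected shared and
unshared genetic variances of trait i are w_i^2 h_i^2 and
(1 - w_i^2) h_i^2.  Genotypes are independent across SNPs (no LD); one
synthetic chromosome with 10 kb spacing makes distance-based pruning and
clumping meaningful on simulated output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from shaher.core import CorrelationMatrix
from shaher.sumstats import SummaryStats

__all__ = ["SimulatedCohort", "simulate_cohort", "gwas_linear", "gwas_of_values"]

logger = logging.getLogger(__name__)

_SPACING_BP = 10_000


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated sample of N individuals, M SNPs and K standardized traits."""

    genotypes: np.ndarray  # N x M column-standardized dosages
    dosages: np.ndarray  # N x M raw 0/1/2 dosages
    traits: np.ndarray  # N x K standardized trait values
    eaf: np.ndarray  # M simulated effect-allele frequencies
    m0: int
    beta0: np.ndarray  # M0 shared effects (common to all traits)
    beta1: np.ndarray  # M1 x K unshared effects
    w: np.ndarray
    h2: np.ndarray
    genetic_values: np.ndarray  # N x K total genetic component per trait
    shared_values: np.ndarray  # N x K shared genetic component per trait

    @property
    def n(self) -> int:
        return self.traits.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    @property
    def k(self) -> int:
        return self.traits.shape[1]


def _chol(mat: CorrelationMatrix) -> np.ndarray:
    try:
        return np.linalg.cholesky(mat.values)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc


def simulate_cohort(
    n: int,
    m0: int,
    m1: int,
    w: Sequence[float],
    h2: Sequence[float],
    uunsh: CorrelationMatrix,
    uenv: CorrelationMatrix,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedCohort:
    """Simulate genotypes and K correlated traits under the shared/unshared model.

    Trait i is assembled as

        y_i = w_i h_i G0 beta0 / sqrt(M0)
            + sqrt(1 - w_i^2) h_i G1 beta1_i / sqrt(M1)
            + sqrt(1 - h_i^2) eps_i

    and then re-standardized empirically (the unit-variance model holds only
    in expectation at finite M and N).
    """
    rng = np.random.default_rng() if rng is None else rng
    w = np.asarray(w, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    k = w.shape[0]
    if h2.shape != (k,) or uunsh.k != k or uenv.k != k:
        raise ValueError("w, h2 and matrix dimensions disagree")
    if np.any(np.abs(w) > 1.0) or np.any(h2 < 0.0) or np.any(h2 > 1.0):
        raise ValueError("require |w_i| <= 1 and h2 in [0, 1]")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("MAFs must satisfy 0 < maf_low <= maf_high <= 0.5")
    if m0 < 1 or m1 < 1 or n < 10:
        raise ValueError("need m0 >= 1, m1 >= 1 and n >= 10")

    m = m0 + m1
    maf = rng.uniform(maf_low, maf_high, size=m)
    dosages = rng.binomial(2, maf, size=(n, m)).astype(float)
    mean = dosages.mean(axis=0)
    sd = dosages.std(axis=0)
    geno = np.zeros_like(dosages)
    poly = sd > 0
    geno[:, poly] = (dosages[:, poly] - mean[poly]) / sd[poly]

    h = np.sqrt(h2)
    beta0 = rng.standard_normal(m0)
    beta1 = rng.standard_normal((m1, k)) @ _chol(uunsh).T
    eps = rng.standard_normal((n, k)) @ _chol(uenv).T

    g0 = geno[:, :m0] @ beta0 / np.sqrt(m0)  # shared genetic impact (SGI)
    g1 = geno[:, m0:] @ beta1 / np.sqrt(m1)
    shared = np.outer(g0, w * h)
    genetic = shared + g1 * (np.sqrt(1.0 - w**2) * h)
    traits = genetic + eps * np.sqrt(1.0 - h2)
    traits = (traits - traits.mean(axis=0)) / traits.std(axis=0)

    return SimulatedCohort(
        genotypes=geno,
        dosages=dosages,
        traits=traits,
        eaf=dosages.mean(axis=0) / 2.0,
        m0=m0,
        beta0=beta0,
        beta1=beta1,
        w=w,
        h2=h2,
        genetic_values=genetic,
        shared_values=shared,
    )


def gwas_of_values(
    cohort: SimulatedCohort, y: np.ndarray, trait: str = "trait"
) -> SummaryStats:
    """Per-SNP simple linear regression of an arbitrary phenotype vector.

    Regression is on the unstandardized dosage with an intercept; beta, SE,
    z, p and per-SNP N are recorded.  Monomorphic SNPs are dropped with a
    logged count.  Variant ids and positions are deterministic: one
    synthetic chromosome, 10 kb spacing.
    """
    y = np.asarray(y, dtype=float)
    n = cohort.n
    if y.shape != (n,):
        raise ValueError("phenotype length does not match the cohort")
    x = cohort.dosages
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=0)
    poly = sxx > 0
    dropped = int((~poly).sum())
    if dropped:
        logger.info("gwas_linear: dropped %d monomorphic SNP(s)", dropped)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    beta = np.where(poly, sxy / np.where(poly, sxx, 1.0), np.nan)
    ss_res = np.maximum(syy - beta**2 * sxx, 0.0)
    sigma2 = ss_res / (n - 2)
    se = np.sqrt(np.where(poly, sigma2 / np.where(poly, sxx, 1.0), np.nan))
    idx = np.flatnonzero(poly & (se > 0))
    z = beta[idx] / se[idx]
    return SummaryStats.from_arrays(
        rsid=np.array([f"rs{j + 1}" for j in idx]),
        chrom=np.full(idx.shape, "1"),
        pos=1 + _SPACING_BP * idx,
        ea=np.full(idx.shape, "A"),
        oa=np.full(idx.shape, "G"),
        eaf=cohort.eaf[idx],
        z=z,
        n=np.full(idx.shape, float(n)),
        beta=beta[idx],
        se=se[idx],
        trait=trait,
    )


def gwas_linear(
    cohort: SimulatedCohort, trait_index: int, trait: Optional[str] = None
) -> SummaryStats:
    """GWAS of one simulated trait (see :func:`gwas_of_values`)."""
    if not (0 <= trait_index < cohort.k):
        raise IndexError("trait index out of range")
    name = trait if trait is not None else f"T{trait_index + 1}"
    return gwas_of_values(cohort, cohort.traits[:, trait_index], trait=name)
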