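"""Domain types and the algebra of the shared-heredity correlation model.

The model partitions the phenotypic correlation matrix of K standardized
traits into genetic and environmental components, and further splits the
genetic correlation matrix into a rank-one part driven by shared genetic
factors (SGF) and a residual part driven by unshared genetic factors (UGF):

    U_phen = H U_gen H + E U_env E,        H = diag(h_i),  E = diag(sqrt(1 - h_i^2))
    U_gen  = w w^T + D U_unsh D,           D = diag(sqrt(1 - w_i^2))

where h_i^2 is the heritability of trait i and w_i^2 is the proportion of
that heritability explained by SGF (w_i carries the sign of the SGF effect
on trait i).  All traits are treated as standardized to unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CorrelationMatrix",
    "TraitPanel",
    "SharedDecomposition",
    "CombinationWeights",
    "HeritabilitySummary",
    "compose_ugen",
    "compose_uphen",
    "combo_moments",
    "DegenerateCombinationError",
]

#: eigenvalue tolerance below which a correlation matrix is flagged not PD
PD_TOL = 1e-8

_SYM_TOL = 1e-10


class DegenerateCombinationError(ValueError):
    """Raised when a linear combination of traits has (near-)zero variance."""


def _as_square(values: np.ndarray) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class CorrelationMatrix:
    """A validated K x K trait-trait correlation matrix.

    Symmetry and a unit diagonal are enforced at construction (tolerance
    1e-10); entries must lie in [-1, 1].  ``pd_ok`` records whether the
    smallest eigenvalue exceeds ``pd_tol`` — validity is a flag, not a hard
    requirement, because downstream stages decide how to treat indefinite
    inputs.
    """

    values: np.ndarray
    pd_tol: float = PD_TOL
    pd_ok: bool = field(init=False)
    min_eigenvalue: float = field(init=False)

    def __post_init__(self) -> None:
        a = _as_square(self.values)
        if not np.allclose(a, a.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("correlation matrix is not symmetric within 1e-10")
        if not np.allclose(np.diag(a), 1.0, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("correlation matrix diagonal is not 1 within 1e-10")
        if np.any(np.abs(a) > 1.0 + _SYM_TOL):
            raise ValueError("correlation entries must lie in [-1, 1]")
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
        a = np.clip(a, -1.0, 1.0)
        a.flags.writeable = False
        object.__setattr__(self, "values", a)
        w = np.linalg.eigvalsh(a)
        object.__setattr__(self, "min_eigenvalue", float(w[0]))
        object.__setattr__(self, "pd_ok", bool(w[0] > self.pd_tol))

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries, row-major order."""
        iu = np.triu_indices(self.k, k=1)
        return self.values[iu]

    @classmethod
    def identity(cls, k: int) -> "CorrelationMatrix":
        return cls(np.eye(k))


@dataclass(frozen=True)
class TraitPanel:
    """Trait names, heritabilities and the two input correlation matrices.

    The framework requires at least three traits: with fewer, the rank-one
    shared component is not identifiable from the genetic correlations.
    """

    names: tuple
    h2: np.ndarray
    ugen: CorrelationMatrix
    uphen: CorrelationMatrix

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        h2 = np.asarray(self.h2, dtype=float)
        k = len(names)
        if k < 3:
            raise ValueError("the framework requires at least three traits")
        if h2.shape != (k,):
            raise ValueError("h2 length does not match the number of traits")
        if np.any(h2 <= 0.0) or np.any(h2 > 1.0):
            raise ValueError("heritabilities must lie in (0, 1]")
        if self.ugen.k != k or self.uphen.k != k:
            raise ValueError("matrix dimensions do not match the number of traits")
        h2 = h2.copy()
        h2.flags.writeable = False
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "h2", h2)

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def hmat(self) -> np.ndarray:
        """H = diag(h_i) with h_i the square root of the heritability."""
        return np.diag(np.sqrt(self.h2))

    @property
    def cgen(self) -> np.ndarray:
        """Genetic covariance matrix C_gen = H U_gen H of standardized traits."""
        h = np.sqrt(self.h2)
        return self.ugen.values * np.outer(h, h)


@dataclass(frozen=True)
class SharedDecomposition:
    """Result of fitting the rank-one shared component to U_gen.

    ``w`` holds the signed square roots of the per-trait proportion of
    heritability explained by SGF, canonicalized so that sum(w) >= 0;
    ``uunsh`` is the recovered unshared genetic correlation matrix and
    ``loss`` the residual sum of squared off-diagonal deviations.
    """

    w: np.ndarray
    uunsh: CorrelationMatrix
    loss: float
    boundary: bool = False
    n_starts: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if np.any(np.abs(w) > 1.0):
            raise ValueError("|w_i| must not exceed 1")
        if w.sum() < 0.0:
            raise ValueError("w must be sign-canonicalized (sum of entries >= 0)")
        if self.loss < 0.0:
            raise ValueError("loss must be nonnegative")
        w = w.copy()
        w.flags.writeable = False
        object.__setattr__(self, "w", w)

    @property
    def w2(self) -> np.ndarray:
        """Per-trait proportion of heritability explained by SGF."""
        return self.w**2


@dataclass(frozen=True)
class CombinationWeights:
    """Coefficients defining SGIT and the per-trait UGITs.

    ``alpha`` combines the original traits into SGIT (normalized to unit
    phenotypic variance); ``c[i]`` is the impact of SGIT on trait i; column i
    of ``gamma = I - alpha c^T`` combines the original traits into UGIT_i.
    """

    alpha: np.ndarray
    c: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        c = np.asarray(self.c, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        k = alpha.shape[0]
        if c.shape != (k,) or gamma.shape != (k, k):
            raise ValueError("alpha, c and gamma dimensions disagree")
        expected = np.eye(k) - np.outer(alpha, c)
        if not np.array_equal(gamma, expected):
            raise ValueError("gamma must equal I - alpha c^T exactly")
        for arr in (alpha, c, gamma):
            arr.flags.writeable = False
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "gamma", gamma)

    @classmethod
    def from_alpha_c(cls, alpha: np.ndarray, c: np.ndarray) -> "CombinationWeights":
        alpha = np.asarray(alpha, dtype=float)
        c = np.asarray(c, dtype=float)
        gamma = np.eye(alpha.shape[0]) - np.outer(alpha, c)
        return cls(alpha=alpha, c=c, gamma=gamma)


@dataclass(frozen=True)
class HeritabilitySummary:
    """Variance moments of a linear combination of the original traits."""

    var_phen: float
    h2_total: float
    h2_shared: float
    q: float

    def __post_init__(self) -> None:
        tol = 1e-8
        if self.var_phen <= 0.0:
            raise ValueError("phenotypic variance must be positive")
        if not (-tol <= self.h2_shared <= self.h2_total + tol):
            raise ValueError("requires 0 <= h2_shared <= h2_total")
        if self.h2_total > 1.0 + 1e-6:
            raise ValueError("total heritability exceeds 1")

    @property
    def h2_unshared(self) -> float:
        return self.h2_total - self.h2_shared


def _check_w(w: Sequence[float]) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 1:
        raise ValueError("w must be a vector")
    if np.any(np.abs(w) > 1.0 + 1e-12):
        raise ValueError("|w_i| must not exceed 1")
    return np.clip(w, -1.0, 1.0)


def compose_ugen(w: Sequence[float], uunsh: CorrelationMatrix) -> CorrelationMatrix:
    """Assemble U_gen = w w^T + D U_unsh D with D = diag(sqrt(1 - w_i^2)).

    The diagonal is exactly 1 by the identity w_i^2 + (1 - w_i^2) = 1.
    """
    w = _check_w(w)
    if uunsh.k != w.shape[0]:
        raise ValueError("w length does not match U_unsh dimension")
    d = np.sqrt(1.0 - w**2)
    out = np.outer(w, w) + uunsh.values * np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return CorrelationMatrix(out)


def compose_uphen(
    ugen: CorrelationMatrix, uenv: CorrelationMatrix, h2: Sequence[float]
) -> CorrelationMatrix:
    """Assemble U_phen = H U_gen H + E U_env E, H = diag(h_i), E = diag(sqrt(1-h_i^2))."""
    h2 = np.asarray(h2, dtype=float)
    if np.any(h2 < 0.0) or np.any(h2 > 1.0):
        raise ValueError("heritabilities must lie in [0, 1]")
    if ugen.k != h2.shape[0] or uenv.k != h2.shape[0]:
        raise ValueError("h2 length does not match matrix dimensions")
    h = np.sqrt(h2)
    e = np.sqrt(1.0 - h2)
    out = ugen.values * np.outer(h, h) + uenv.values * np.outer(e, e)
    np.fill_diagonal(out, 1.0)
    return CorrelationMatrix(out)


def combo_moments(
    k: Sequence[float], panel: TraitPanel, w: Sequence[float]
) -> HeritabilitySummary:
    """Analytic variance moments of the combination k^T y.

    Given the panel's matrices and the SGF loadings w, the phenotypic
    variance is k^T U_phen k, the genetic variance k^T H U_gen H k, and the
    shared genetic variance the squared projection (k^T H w)^2 of the
    combination onto the shared factor direction.
    """
    kvec = np.asarray(k, dtype=float)
    w = _check_w(w)
    if kvec.shape != (panel.k,) or w.shape != (panel.k,):
        raise ValueError("coefficient/w vector length does not match the panel")
    if not np.any(kvec):
        raise ValueError("combination coefficients must not all be zero")
    var_phen = float(kvec @ panel.uphen.values @ kvec)
    if var_phen <= 1e-12:
        raise DegenerateCombinationError(
            f"combination has near-zero phenotypic variance ({var_phen:.3e})"
        )
    cgen = panel.cgen
    var_gen = float(kvec @ cgen @ kvec)
    hw = np.sqrt(panel.h2) * w
    var_shared = float(kvec @ hw) ** 2
    h2_total = max(var_gen, 0.0) / var_phen
    h2_shared = var_shared / var_phen
    # guard against float noise in the Cauchy-Schwarz bound shared <= total
    h2_shared = min(h2_shared, h2_total)
    q = h2_shared / h2_total if h2_total > 0.0 else 0.0
    return HeritabilitySummary(
        var_phen=var_phen,
        h2_total=min(h2_total, 1.0),
        h2_shared=h2_shared,
        q=float(min(max(q, 0.0), 1.0)),
    )
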