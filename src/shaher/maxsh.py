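"""MaxSH: estimate the shared-factor loadings and build SGIT/UGIT weights.

The stage proceeds in four steps.  First the per-trait loadings w are
estimated by fitting the rank-one model w w^T to the off-diagonal of the
genetic correlation matrix (least squares, bounded multi-start
quasi-Newton).  Second, the SGIT combination coefficients alpha are the
closed-form maximizer of the shared-heritability ratio

    alpha = U_phen^{-1} H w / sqrt(w^T H U_phen^{-1} H w),

normalized so SGIT has unit phenotypic variance.  Third, each UGIT is the
residual of its trait after removing the genetic projection on SGIT,
UGIT_i = y_i - c_i SGIT with c_i = cov_gen(y_i, SGIT) / h2_SGIT, encoded by
the columns of Gamma = I - alpha c^T.  Finally the screen is re-run on the
genetic correlations between UGITs to verify that no shared impact remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from shaher.core import (
    CombinationWeights,
    CorrelationMatrix,
    HeritabilitySummary,
    SharedDecomposition,
    TraitPanel,
    combo_moments,
)
from shaher.screen import DEFAULT_SGI_THRESHOLD, SgiVerdict, check_sgi

__all__ = [
    "loss_value",
    "estimate_w",
    "solve_alpha",
    "solve_ugit_weights",
    "run_maxsh",
    "MaxshReport",
    "SgiScreenError",
    "OptimizationError",
]

_BOX_EPS = 1e-6
_TIE_TOL = 1e-12
_START_MAGNITUDES = (0.3, 0.5, 0.7, 0.9)


class SgiScreenError(RuntimeError):
    """The SGI screen rejected the genetic correlation matrix."""

    def __init__(self, verdict: SgiVerdict):
        self.verdict = verdict
        super().__init__("SGI screen failed:\n" + verdict.describe())


class OptimizationError(RuntimeError):
    """The loss minimization failed to converge from every start."""


def _offdiag_indices(k: int) -> Tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(k, k=1)


def loss_value(w: Sequence[float], ugen: CorrelationMatrix) -> float:
    """Sum of squared off-diagonal deviations between U_gen and V = w w^T + (I - diag(w^2)).

    The diagonals of V and U_gen agree identically, so only pairs i < j
    contribute.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (ugen.k,):
        raise ValueError("w length does not match the matrix dimension")
    if np.any(np.abs(w) > 1.0 + 1e-12):
        raise ValueError("|w_i| must not exceed 1")
    iu = _offdiag_indices(ugen.k)
    resid = ugen.values[iu] - np.outer(w, w)[iu]
    return float(resid @ resid)


def _loss_and_grad(w: np.ndarray, r: np.ndarray) -> Tuple[float, np.ndarray]:
    """Loss and its analytic gradient; ``r`` is U_gen with zeroed diagonal."""
    outer = np.outer(w, w)
    np.fill_diagonal(outer, 0.0)
    resid = r - outer
    loss = 0.5 * float((resid * resid).sum())  # each pair counted twice
    grad = -2.0 * (resid @ w)
    return loss, grad


def _start_points(ugen: CorrelationMatrix) -> np.ndarray:
    """Multi-start grid: 4 magnitudes x sign patterns (screen signs and all-ones, both polarities)."""
    k = ugen.k
    signs = np.sign(ugen.values[0]).astype(float)
    signs[signs == 0.0] = 1.0
    signs[0] = 1.0
    patterns = {tuple(signs), tuple(-signs), tuple(np.ones(k)), tuple(-np.ones(k))}
    starts = [
        m * np.asarray(p) for m in _START_MAGNITUDES for p in sorted(patterns)
    ]
    return np.asarray(starts)


def estimate_w(
    ugen: CorrelationMatrix,
    box_eps: float = _BOX_EPS,
    ftol: float = 1e-14,
    gtol: float = 1e-10,
) -> SharedDecomposition:
    """Estimate the shared-factor loadings w by bounded least squares on U_gen.

    Minimizes sum_{i<j} (r_ij - w_i w_j)^2 over w in [-1+eps, 1-eps]^K from
    multiple starts (four magnitudes crossed with candidate sign patterns);
    the best minimum wins, ties within 1e-12 resolved toward the larger
    ||w||^2.  The result is sign-canonicalized (sum w_i >= 0) and the
    unshared correlation matrix is recovered as
    D^{-1} (U_gen - w w^T) D^{-1}, D = diag(sqrt(1 - w_i^2)), with its
    diagonal forced to one and off-diagonals clipped to [-1, 1].
    """
    k = ugen.k
    r = ugen.values.copy()
    np.fill_diagonal(r, 0.0)
    bounds = [(-1.0 + box_eps, 1.0 - box_eps)] * k

    best_w: Optional[np.ndarray] = None
    best_loss = np.inf
    n_ok = 0
    messages = []
    for x0 in _start_points(ugen):
        res = minimize(
            _loss_and_grad,
            np.clip(x0, -1.0 + box_eps, 1.0 - box_eps),
            args=(r,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": ftol, "gtol": gtol, "maxiter": 500},
        )
        if not res.success and not np.isfinite(res.fun):
            messages.append(str(res.message))
            continue
        n_ok += 1
        if res.fun < best_loss - _TIE_TOL:
            best_loss, best_w = float(res.fun), res.x
        elif abs(res.fun - best_loss) <= _TIE_TOL and best_w is not None:
            if res.x @ res.x > best_w @ best_w:
                best_loss, best_w = float(res.fun), res.x
        if best_loss < 1e-13:
            break
    if best_w is None:
        raise OptimizationError(
            f"no start converged out of {len(_start_points(ugen))}: {messages}"
        )

    w = best_w if best_w.sum() >= 0.0 else -best_w
    boundary = bool(np.any(np.abs(w) >= 1.0 - 2.0 * box_eps))
    if boundary:
        warnings.warn(
            "estimated |w_i| at the box boundary: heritability fully shared "
            "for at least one trait",
            RuntimeWarning,
            stacklevel=2,
        )

    d = np.sqrt(1.0 - w**2)
    uu = (ugen.values - np.outer(w, w)) / np.outer(d, d)
    uu = np.clip((uu + uu.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(uu, 1.0)
    return SharedDecomposition(
        w=w,
        uunsh=CorrelationMatrix(uu),
        loss=loss_value(w, ugen),
        boundary=boundary,
        n_starts=n_ok,
    )


def solve_alpha(panel: TraitPanel, w: Sequence[float]) -> np.ndarray:
    """Closed-form SGIT coefficients maximizing the shared-heritability ratio.

    alpha maximizes (k^T H w)^2 / (k^T U_phen k) over all combinations k;
    the normalization makes SGIT's phenotypic variance exactly one.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (panel.k,):
        raise ValueError("w length does not match the panel")
    hw = np.sqrt(panel.h2) * w
    if not np.any(hw):
        raise ValueError("w is zero: no shared component to maximize")
    if not panel.uphen.pd_ok:
        raise np.linalg.LinAlgError(
            "phenotypic correlation matrix is singular or indefinite "
            f"(min eigenvalue {panel.uphen.min_eigenvalue:.3e})"
        )
    raw = np.linalg.solve(panel.uphen.values, hw)
    denom = float(hw @ raw)
    if denom <= 0.0:
        raise np.linalg.LinAlgError("H w lies in a nonpositive direction of U_phen^{-1}")
    return raw / np.sqrt(denom)


def solve_ugit_weights(
    panel: TraitPanel, alpha: Sequence[float], tol: float = 1e-10
) -> Tuple[np.ndarray, np.ndarray]:
    """SGIT impacts c and UGIT combination matrix Gamma = I - alpha c^T.

    c_i = cov_gen(y_i, SGIT) / h2_SGIT; column i of Gamma encodes
    UGIT_i = y_i - c_i SGIT.  By construction Gamma^T C_gen alpha = 0: every
    UGIT is genetically uncorrelated with SGIT.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (panel.k,):
        raise ValueError("alpha length does not match the panel")
    var_sgit = float(alpha @ panel.uphen.values @ alpha)
    if abs(var_sgit - 1.0) > 1e-8:
        raise ValueError("alpha is not normalized to unit phenotypic variance")
    cgen = panel.cgen
    cov_gen = cgen @ alpha
    h2_sgit = float(alpha @ cov_gen)
    if h2_sgit <= tol:
        raise ValueError(f"SGIT has no genetic variance (h2 = {h2_sgit:.3e})")
    c = cov_gen / h2_sgit
    gamma = np.eye(panel.k) - np.outer(alpha, c)
    return c, gamma


def _ugit_gen_corr(
    panel: TraitPanel, gamma: np.ndarray, h2_tol: float = 1e-8
) -> CorrelationMatrix:
    """Genetic correlations between UGITs, normalizing Gamma^T C_gen Gamma.

    UGITs with genetic variance below ``h2_tol`` get zeroed correlations (a
    0/0 guard) and a warning.
    """
    cov = gamma.T @ panel.cgen @ gamma
    var = np.diag(cov).copy()
    degenerate = var < h2_tol
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} UGIT(s) have genetic variance below "
            f"{h2_tol:g}; their genetic correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    scale = np.where(degenerate, 1.0, np.sqrt(np.maximum(var, h2_tol)))
    corr = cov / np.outer(scale, scale)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr)


@dataclass(frozen=True)
class MaxshReport:
    """Full output of the MaxSH stage for one trait panel."""

    panel: TraitPanel
    screen: SgiVerdict
    decomposition: SharedDecomposition
    weights: CombinationWeights
    sgit: HeritabilitySummary
    ugits: Tuple[HeritabilitySummary, ...]
    ugit_ugen: CorrelationMatrix
    final_screen: SgiVerdict
    gip1: Optional[np.ndarray] = None
    gip1_summary: Optional[HeritabilitySummary] = None

    @property
    def shared_h2(self) -> np.ndarray:
        """Per-trait heritability explained by the shared factor, w_i^2 h_i^2."""
        return self.decomposition.w2 * self.panel.h2

    @property
    def unshared_h2(self) -> np.ndarray:
        return (1.0 - self.decomposition.w2) * self.panel.h2

    def describe(self) -> str:
        p = self.panel
        lines = [self.screen.describe(), ""]
        lines.append("Per-trait decomposition:")
        lines.append("  trait\th2\tw\tw2\tshared_h2\tunshared_h2")
        for i, name in enumerate(p.names):
            lines.append(
                f"  {name}\t{p.h2[i]:.4f}\t{self.decomposition.w[i]:+.4f}"
                f"\t{self.decomposition.w2[i]:.4f}\t{self.shared_h2[i]:.4f}"
                f"\t{self.unshared_h2[i]:.4f}"
            )
        lines.append(f"  loss: {self.decomposition.loss:.6g}")
        lines.append("")
        lines.append(
            f"SGIT: h2_total={self.sgit.h2_total:.4f} "
            f"h2_shared={self.sgit.h2_shared:.4f} Q={self.sgit.q:.4f}"
        )
        for name, s in zip(p.names, self.ugits):
            lines.append(
                f"UGIT[{name}]: h2_total={s.h2_total:.4f} "
                f"h2_shared={s.h2_shared:.4f}"
            )
        if self.gip1_summary is not None:
            lines.append(
                f"GIP1: h2_total={self.gip1_summary.h2_total:.4f} "
                f"h2_shared={self.gip1_summary.h2_shared:.4f}"
            )
        lines.append("")
        lines.append("Residual SGI screen on UGIT genetic correlations "
                     f"(expected FAIL): {'PASS' if self.final_screen.passed else 'FAIL'}")
        return "\n".join(lines)


def run_maxsh(
    panel: TraitPanel,
    threshold: float = DEFAULT_SGI_THRESHOLD,
    with_gip: bool = False,
) -> MaxshReport:
    """Run the full MaxSH pipeline on a trait panel.

    Screens U_gen for a shared impact (raising :class:`SgiScreenError` when
    it is absent), estimates w, solves for alpha, c and Gamma, summarizes
    SGIT/UGIT heritabilities analytically, and re-screens the UGIT genetic
    correlation matrix to confirm that no residual SGI remains.
    """
    screen = check_sgi(panel.ugen, threshold)
    if not screen.passed:
        raise SgiScreenError(screen)
    decomp = estimate_w(panel.ugen)
    alpha = solve_alpha(panel, decomp.w)
    c, gamma = solve_ugit_weights(panel, alpha)
    weights = CombinationWeights(alpha=alpha, c=c, gamma=gamma)
    sgit = combo_moments(alpha, panel, decomp.w)
    ugits = tuple(
        combo_moments(gamma[:, i], panel, decomp.w) for i in range(panel.k)
    )
    ugit_ugen = _ugit_gen_corr(panel, gamma)
    final_screen = check_sgi(ugit_ugen, threshold)

    gip1 = gip1_summary = None
    if with_gip:
        from shaher.gip import gip1_weights

        gip1 = gip1_weights(panel)
        gip1_summary = combo_moments(gip1, panel, decomp.w)

    return MaxshReport(
        panel=panel,
        screen=screen,
        decomposition=decomp,
        weights=weights,
        sgit=sgit,
        ugits=ugits,
        ugit_ugen=ugit_ugen,
        final_screen=final_screen,
        gip1=gip1,
        gip1_summary=gip1_summary,
    )
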