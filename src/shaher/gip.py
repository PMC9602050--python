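"""GIP1 baseline: first principal component of the genetic covariance matrix.

The genetically independent phenotype (GIP) construction applies principal
component analysis to the genetic covariance matrix C_gen = H U_gen H
rather than to phenotypic correlations.  Its first component is the closest
analogue of SGIT among earlier methods and serves as the comparison
baseline in the simulation study.  The leading eigenvector is rescaled to
unit phenotypic variance so GIP1 and SGIT heritabilities are directly
comparable.
"""

from __future__ import annotations

import numpy as np

from shaher.core import TraitPanel

__all__ = ["gip1_weights", "DegenerateSpectrumError"]


class DegenerateSpectrumError(RuntimeError):
    """The leading eigenvalue of C_gen is not unique; GIP1 is undefined."""


def gip1_weights(panel: TraitPanel, tol: float = 1e-10) -> np.ndarray:
    """Combination coefficients of GIP1, normalized to unit phenotypic variance.

    Returns beta = v / sqrt(v^T U_phen v) where v is the leading eigenvector
    of C_gen, with the sign fixed so that sum(beta) >= 0.  Raises
    :class:`DegenerateSpectrumError` when the top two eigenvalues coincide
    within ``tol``.
    """
    eigval, eigvec = np.linalg.eigh(panel.cgen)
    if eigval[-1] - eigval[-2] <= tol:
        raise DegenerateSpectrumError(
            f"leading eigenvalue is degenerate: top two eigenvalues "
            f"{eigval[-1]:.6g} and {eigval[-2]:.6g} differ by less than {tol:g}"
        )
    v = eigvec[:, -1]
    var = float(v @ panel.uphen.values @ v)
    if var <= 0.0:
        raise np.linalg.LinAlgError("GIP1 has nonpositive phenotypic variance")
    beta = v / np.sqrt(var)
    if beta.sum() < 0.0:
        beta = -beta
    return beta
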