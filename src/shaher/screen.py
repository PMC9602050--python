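"""Preliminary screen for the presence of a shared genetic impact (SGI).

A rank-one shared factor can only be supported by a genetic correlation
matrix that (a) is positive definite, (b) has no off-diagonal correlation
whose magnitude falls at or below a threshold (default 0.2), and (c) has a
sign pattern consistent with a rank-one matrix: there must exist a sign
vector s in {-1, +1}^K with sign(r_ij) = s_i s_j for every pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from shaher.core import CorrelationMatrix

__all__ = ["SgiVerdict", "check_sgi", "DEFAULT_SGI_THRESHOLD"]

#: correlation-magnitude threshold for confirming the existence of an SGI
DEFAULT_SGI_THRESHOLD = 0.2


@dataclass(frozen=True)
class SgiVerdict:
    """Outcome of the SGI screen with per-requirement diagnostics."""

    passed: bool
    pd_ok: bool
    min_abs_offdiag: float
    threshold: float
    sign_rank1_ok: bool
    sign_vector: Optional[np.ndarray]

    def describe(self) -> str:
        lines = [
            f"SGI screen: {'PASS' if self.passed else 'FAIL'}",
            f"  positive definite:        {self.pd_ok}",
            f"  min |off-diagonal|:       {self.min_abs_offdiag:.6g} "
            f"(threshold {self.threshold:g})",
            f"  rank-one sign pattern:    {self.sign_rank1_ok}",
        ]
        if self.sign_vector is not None:
            signs = "".join("+" if s > 0 else "-" for s in self.sign_vector)
            lines.append(f"  sign vector:              {signs}")
        return "\n".join(lines)


def _rank1_signs(values: np.ndarray) -> Optional[np.ndarray]:
    """Sign vector s with sign(r_ij) = s_i s_j for all i != j, or None.

    Constructed as s_1 = +1, s_i = sign(r_1i), then verified on every pair.
    Any exact zero off-diagonal defeats the construction.
    """
    k = values.shape[0]
    signs = np.sign(values)
    iu = np.triu_indices(k, k=1)
    if np.any(signs[iu] == 0.0):
        return None
    s = np.ones(k)
    s[1:] = signs[0, 1:]
    if np.all(signs[iu] == np.outer(s, s)[iu]):
        return s
    return None


def check_sgi(
    ugen: CorrelationMatrix, threshold: float = DEFAULT_SGI_THRESHOLD
) -> SgiVerdict:
    """Screen a genetic correlation matrix for the presence of an SGI.

    ``threshold`` applies to the absolute values of the off-diagonal
    correlations; direction consistency is handled separately by the
    rank-one sign test, so traits negatively coupled to the shared factor
    are accepted.
    """
    if ugen.k < 3:
        raise ValueError("the SGI screen requires at least three traits")
    off = ugen.offdiag()
    min_abs = float(np.min(np.abs(off)))
    sign_vector = _rank1_signs(ugen.values)
    sign_ok = sign_vector is not None
    passed = bool(ugen.pd_ok and (min_abs > threshold) and sign_ok)
    return SgiVerdict(
        passed=passed,
        pd_ok=ugen.pd_ok,
        min_abs_offdiag=min_abs,
        threshold=float(threshold),
        sign_rank1_ok=sign_ok,
        sign_vector=sign_vector,
    )
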