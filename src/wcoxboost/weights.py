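"""Two-level observation weighting for the stratified partial likelihood.

Observations in the focus stratum carry weight 1; all other observations
carry a common down-weight ``w`` in [0, 1].  ``w=1`` recovers the global
stratified analysis, ``w=0`` the focus-subgroup-only analysis, and values
in between borrow a controlled amount of information from the other strata.

Weight vectors are only defined up to a common positive factor in the
partial likelihood machinery, so the scheme is stored in canonical form:
focus weight exactly 1.  ``from_vector`` canonicalizes an explicit weight
vector accordingly, which makes likelihood/score/information values
invariant to global rescaling of the input weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WeightScheme"]


@dataclass(frozen=True)
class WeightScheme:
    """Down-weighting scheme: weight 1 on the focus stratum, ``w`` elsewhere."""

    w: float = 1.0
    focus_stratum: int = 1

    def __post_init__(self):
        if not (0.0 <= self.w <= 1.0):
            raise ValueError(f"down-weight w must lie in [0, 1], got {self.w}")

    def weights(self, strata: np.ndarray) -> np.ndarray:
        """Per-observation weight vector for the given stratum labels."""
        strata = np.asarray(strata)
        if not np.any(strata == self.focus_stratum):
            raise ValueError(f"focus stratum {self.focus_stratum} absent from data")
        return np.where(strata == self.focus_stratum, 1.0, float(self.w))

    @classmethod
    def from_vector(cls, weights, strata, focus_stratum: int = 1) -> "WeightScheme":
        """Canonicalize an explicit two-level weight vector into a scheme.

        The vector may be scaled by any positive constant; it is divided by
        the (common) focus-stratum weight.  A vector that is not two-level
        with constant weight within focus/non-focus groups is rejected.
        """
        weights = np.asarray(weights, dtype=float)
        strata = np.asarray(strata)
        focus = strata == focus_stratum
        if not focus.any():
            raise ValueError(f"focus stratum {focus_stratum} absent from data")
        wf = np.unique(weights[focus])
        if wf.size != 1 or wf[0] <= 0:
            raise ValueError("focus-stratum weights must share one positive value")
        rest = np.unique(weights[~focus]) if (~focus).any() else np.array([wf[0]])
        if rest.size > 1:
            raise ValueError("non-focus weights must share one common value")
        w = float(rest[0] / wf[0]) if rest.size else 1.0
        return cls(w=w, focus_stratum=focus_stratum)
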