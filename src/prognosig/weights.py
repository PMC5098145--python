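"""Prognostic-variable weight schemes.

Six ways of quantifying the relative importance of each variable in the
multivariate classifier, all derived from the univariate fit's Wald
p-value P_i and hazard ratio HR_i and all normalized to sum to 1:

=======  ==============================  ==========================
scheme   name                            raw weight
=======  ==============================  ==========================
A        constant                        1
B        inverse P                       1 / P_i
C        negative log P                  -log P_i
D        hazard ratio                    HR_i
E        (-log P) x HR, multiplicative   nlp~_i * hr~_i
F        (-log P) + HR, additive         (nlp~_i + hr~_i) / 2
=======  ==============================  ==========================

where ``nlp~`` and ``hr~`` are the -log P and HR vectors each first
normalized to sum 1 so that the two quantity scales combine comparably;
this component normalization also makes every scheme invariant to the
logarithm base. The final vector is renormalized to sum 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["WeightVector", "compute_weights", "weight_dynamic_range", "SCHEMES"]

SCHEMES = ("A", "B", "C", "D", "E", "F")

#: smallest admissible p-value; upstream fits reporting exact 0 are floored here
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class WeightVector:
    """Normalized per-variable importance weights under one scheme."""

    scheme: str
    variable_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size != len(self.variable_ids):
            raise ValueError("weights must align with variable_ids")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size


def _normalize(raw: np.ndarray) -> np.ndarray:
    return raw / raw.sum()


def compute_weights(
    p_values: np.ndarray,
    hazard_ratios: np.ndarray,
    scheme: str,
    variable_ids: tuple[str, ...] | None = None,
) -> WeightVector:
    """Compute one of the six weight schemes, normalized to sum 1.

    ``p_values`` must lie strictly inside (0, 1) — an exact 0 arising
    from an upstream fit is floored at 1e-300 with a warning, an exact
    1 is an error. ``hazard_ratios`` must be positive (schemes D-F).
    """
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}; choose from {SCHEMES}")
    p = np.asarray(p_values, dtype=float)
    hr = np.asarray(hazard_ratios, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if hr.shape != p.shape:
        raise ValueError("hazard_ratios must align with p_values")
    if np.any(p == 0):
        warnings.warn(
            "p-values numerically 0 floored at 1e-300 for weighting",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.maximum(p, _P_FLOOR)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p_values must lie strictly in (0, 1)")
    if scheme in ("D", "E", "F") and np.any(hr <= 0):
        raise ValueError("hazard_ratios must be > 0")

    if scheme == "A":
        raw = np.ones_like(p)
    elif scheme == "B":
        raw = 1.0 / p
    elif scheme == "C":
        raw = -np.log(p)
    elif scheme == "D":
        raw = hr.copy()
    else:
        nlp = _normalize(-np.log(p))
        hrn = _normalize(hr)
        raw = nlp * hrn if scheme == "E" else (nlp + hrn) / 2.0

    ids = variable_ids or tuple(f"v{i + 1}" for i in range(p.size))
    return WeightVector(scheme=scheme, variable_ids=tuple(ids), weights=_normalize(raw))


def weight_dynamic_range(w: WeightVector) -> float:
    """max(weight) / min(weight): how concentrated the scheme is on its
    top variables (1.0 for the constant scheme)."""
    return float(w.weights.max() / w.weights.min())
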