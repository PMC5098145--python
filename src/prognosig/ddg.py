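"""One-dimensional data-driven grouping (1D-DDg).

The univariate survival classifier: scan every admissible cutoff of a
continuous variable, dichotomize the cohort at each (value <= cutoff vs
value > cutoff), fit a binary-covariate Cox model, and keep the cutoff
whose Wald p-value is smallest. The *design* records the direction of
risk at the optimum:

* design 1 ("supp-like"): low values carry the high risk;
* design 2 ("onco-like"): high values carry the high risk.

The hazard ratio is always reported for the high-risk subgroup relative
to the low-risk subgroup and is therefore >= 1.

Because the optimal cutoff is selected by minimizing p over many
dependent tests, the reported minimal p is anti-conservative under the
null of no association; it is used here, as in the source methodology,
as a relative ranking/weighting quantity, not as a calibrated
significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survival import CoxFit, SurvivalData, fit_binary_cox

__all__ = ["DDgModel", "candidate_cutoffs", "fit_1d_ddg", "apply_1d_ddg"]

DESIGN_LOW_IS_HIGH_RISK = 1  # "supp-like"
DESIGN_LOW_IS_LOW_RISK = 2  # "onco-like"

_BEHAVIOUR = {1: "supp-like", 2: "onco-like"}


@dataclass(frozen=True)
class DDgModel:
    """A fitted univariate cutoff classifier for one variable."""

    variable_id: str
    cutoff: float
    design: int
    wald_p: float
    hazard_ratio: float
    n_low_risk: int
    n_high_risk: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.design not in (1, 2):
            raise ValueError("design must be 1 or 2")
        if self.hazard_ratio < 1.0:
            raise ValueError("hazard_ratio is reported high- vs low-risk and must be >= 1")

    @property
    def behaviour(self) -> str:
        return _BEHAVIOUR[self.design]


def candidate_cutoffs(values: np.ndarray, min_fraction: float = 0.05) -> np.ndarray:
    """Admissible cutoffs for a variable: midpoints between consecutive
    distinct sorted values, keeping only splits that leave at least
    ``ceil(min_fraction * M)`` patients on each side.

    An all-constant variable yields an empty array (degenerate).
    """
    if not 0 < min_fraction < 0.5:
        raise ValueError("min_fraction must be in (0, 0.5)")
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    srt = np.sort(values)
    distinct = np.unique(srt)
    if distinct.size < 2:
        return np.empty(0)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    m = values.size
    min_n = int(np.ceil(min_fraction * m))
    # patients with value <= cutoff on the low side
    n_low = np.searchsorted(srt, mids, side="right")
    ok = (n_low >= min_n) & (m - n_low >= min_n)
    return mids[ok]


def _orient(fit: CoxFit, cutoff: float, n_above: int, n_total: int, variable_id: str, description: str) -> DDgModel:
    """Turn a Cox fit with covariate 1{value > cutoff} into a DDgModel.

    beta > 0 means the upper side has the higher hazard (design 2);
    beta < 0 means the lower side does (design 1). HR is re-expressed
    high-risk vs low-risk, hence >= 1. beta == 0 defaults to design 2.
    """
    if fit.beta >= 0:
        design = DESIGN_LOW_IS_LOW_RISK
        hr = fit.hazard_ratio
        n_high = n_above
    else:
        design = DESIGN_LOW_IS_HIGH_RISK
        hr = 1.0 / fit.hazard_ratio
        n_high = n_total - n_above
    return DDgModel(
        variable_id=variable_id,
        cutoff=float(cutoff),
        design=design,
        wald_p=fit.wald_p,
        hazard_ratio=float(hr),
        n_low_risk=n_total - n_high,
        n_high_risk=n_high,
        description=description,
    )


def fit_1d_ddg(
    values: np.ndarray,
    data: SurvivalData,
    min_fraction: float = 0.05,
    *,
    variable_id: str = "variable",
    description: str = "",
    ties: str = "breslow",
) -> DDgModel:
    """Fit the 1D-DDg classifier: the cutoff minimizing the Wald p-value.

    For every admissible cutoff the cohort is split into (value <=
    cutoff) vs (value > cutoff), a binary Cox model is fitted with the
    upper-side indicator as covariate, and the split with the smallest
    Wald p wins. Ties on p are broken in favour of the most balanced
    subgroup sizes, then the smaller cutoff.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != data.times.shape:
        raise ValueError("values length must match cohort size")
    cuts = candidate_cutoffs(values, min_fraction)
    if cuts.size == 0:
        raise ValueError(
            f"variable {variable_id!r}: no admissible cutoff "
            f"(degenerate values or min_fraction={min_fraction} too large)"
        )

    best: tuple[float, int, float] | None = None  # (p, -balance, cutoff)
    best_fit: CoxFit | None = None
    best_cut = np.nan
    best_n_above = 0
    n = values.size
    for c in cuts:
        above = values > c
        fit = fit_binary_cox(data, above.astype(int), ties=ties)
        n_above = int(above.sum())
        balance = min(n_above, n - n_above)  # larger = more balanced
        key = (fit.wald_p, -balance, c)
        if best is None or key < best:
            best = key
            best_fit = fit
            best_cut = float(c)
            best_n_above = n_above
    assert best_fit is not None
    return _orient(best_fit, best_cut, best_n_above, n, variable_id, description)


def apply_1d_ddg(model: DDgModel, value: float) -> int:
    """Risk call for one patient value: 1 = high risk, 0 = low risk.

    Values exactly at the cutoff fall on the "<= cutoff" side.
    """
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"variable {model.variable_id!r}: non-finite value")
    above = value > model.cutoff
    if model.design == DESIGN_LOW_IS_LOW_RISK:
        return int(above)
    return int(not above)
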