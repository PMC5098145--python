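"""Statistically weighted voting grouping (SWVg).

Each univariate cutoff classifier casts a binary risk vote for every
patient; the votes are combined into the average weighted risk

    AWR = sum_i w_i * s_i,      s_i in {0, 1},  sum_i w_i = 1,

so AWR lies in [0, 1] with 0 = every classifier votes low risk. Two
thresholds on the AWR then stratify the cohort into low, intermediate
and high risk; the thresholds are chosen by exhaustive search to
minimize the 3-group log-rank p-value subject to a minimum group size.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ddg import DDgModel, apply_1d_ddg, fit_1d_ddg
from .survival import LogRankResult, SurvivalData, logrank_test
from .weights import WeightVector, compute_weights

__all__ = [
    "RiskClass",
    "SwvgModel",
    "compute_awr",
    "fit_awr_thresholds",
    "assign_risk_class",
    "fit_swvg",
    "risk_calls_matrix",
]


class RiskClass(enum.IntEnum):
    """Ordered prognostic risk class: LOW < INTERMEDIATE < HIGH."""

    LOW = 0
    INTERMEDIATE = 1
    HIGH = 2

    def __str__(self) -> str:  # tabular output uses the lowercase word
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "RiskClass":
        return cls[label.strip().upper()]


@dataclass(frozen=True)
class SwvgModel:
    """Fitted multivariate risk stratifier.

    Holds the per-variable cutoff classifiers, their weights, and the
    two AWR thresholds (low <= t_low < intermediate <= t_high < high).
    """

    ddg_models: tuple[DDgModel, ...]
    weight_vector: WeightVector
    t_low: float
    t_high: float
    training_logrank: LogRankResult

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be < t_high")
        if len(self.ddg_models) != len(self.weight_vector):
            raise ValueError("weight vector must align with the DDg models")

    @property
    def variable_ids(self) -> tuple[str, ...]:
        return tuple(m.variable_id for m in self.ddg_models)

    def risk_calls(self, patient_values: np.ndarray) -> np.ndarray:
        """Binary risk votes for one patient, aligned to ddg_models."""
        vals = np.asarray(patient_values, dtype=float)
        if vals.size != len(self.ddg_models):
            raise ValueError("patient values must align with the signature")
        return np.array([apply_1d_ddg(m, v) for m, v in zip(self.ddg_models, vals)], dtype=np.int8)

    def predict_awr(self, patient_values: np.ndarray, *, missing: str = "error") -> float:
        """AWR for one patient.

        ``missing="renormalize"`` drops NaN variables and renormalizes
        the remaining weights for this patient only (flagged by a
        warning); the default is to raise on any missing value.
        """
        vals = np.asarray(patient_values, dtype=float)
        ok = np.isfinite(vals)
        if ok.all():
            return compute_awr(self.risk_calls(vals), self.weight_vector)
        if missing != "renormalize":
            bad = [m.variable_id for m, o in zip(self.ddg_models, ok) if not o]
            raise ValueError(f"missing values for variables {bad}")
        if not ok.any():
            raise ValueError("all variable values missing")
        import warnings

        warnings.warn(
            f"AWR computed from {int(ok.sum())}/{ok.size} variables "
            "(missing dropped, weights renormalized)",
            RuntimeWarning,
            stacklevel=2,
        )
        calls = np.array(
            [apply_1d_ddg(m, v) for m, v, o in zip(self.ddg_models, vals, ok) if o]
        )
        w = self.weight_vector.weights[ok]
        return float(np.dot(w / w.sum(), calls))

    def predict_class(self, patient_values: np.ndarray) -> RiskClass:
        return assign_risk_class(self.predict_awr(patient_values), self)


def compute_awr(risk_calls: np.ndarray, w: WeightVector) -> float:
    """Average weighted risk: the weighted mean of the binary votes."""
    s = np.asarray(risk_calls)
    if s.shape != w.weights.shape:
        raise ValueError("risk_calls must align with the weight vector")
    if not np.all(np.isin(s, (0, 1))):
        raise ValueError("risk_calls must be binary")
    return float(np.dot(w.weights, s))


def _threshold_candidates(awr: np.ndarray) -> np.ndarray:
    distinct = np.unique(awr)
    return (distinct[:-1] + distinct[1:]) / 2.0


def fit_awr_thresholds(
    awr: np.ndarray,
    data: SurvivalData,
    min_fraction: float = 0.10,
) -> tuple[float, float, LogRankResult]:
    """Exhaustive search for the AWR threshold pair minimizing the
    3-group log-rank p-value.

    Candidates are midpoints between consecutive distinct AWR values;
    a pair (t_low, t_high) is admissible when each of the three groups
    (awr <= t_low, t_low < awr <= t_high, awr > t_high) has at least
    ``ceil(min_fraction * M)`` patients. Ties on p are broken by
    maximizing the smallest group size, then by the lexicographically
    smaller pair.

    The scan is exact but vectorized: because threshold groups are
    contiguous in AWR rank order, the 3-group log-rank statistic for
    every pair follows from per-event-time prefix sums of the at-risk
    and death indicators over AWR-ranked patients.
    """
    awr = np.asarray(awr, dtype=float)
    if awr.shape != data.times.shape:
        raise ValueError("awr length must match cohort size")
    if data.n_events == 0:
        raise ValueError("no events observed: log-rank test undefined")
    cand = _threshold_candidates(awr)
    if cand.size < 2:
        raise ValueError("need at least 3 distinct AWR values to form 3 groups")
    m = awr.size
    min_n = int(np.ceil(min_fraction * m))
    srt = np.sort(awr)
    n_le = np.searchsorted(srt, cand, side="right")  # group-1 size per candidate

    # prefix sums over AWR-ranked patients at each distinct event time
    order = np.argsort(awr, kind="stable")
    times = data.times[order]
    events = data.events[order]
    tau = np.unique(times[events == 1])  # J distinct event times
    at_risk = times[None, :] >= tau[:, None]  # (J, m)
    death = (times[None, :] == tau[:, None]) & (events[None, :] == 1)
    R = np.zeros((tau.size, m + 1))
    D = np.zeros((tau.size, m + 1))
    R[:, 1:] = np.cumsum(at_risk, axis=1)
    D[:, 1:] = np.cumsum(death, axis=1)
    nj = R[:, m]  # total at risk
    dj = D[:, m]  # total deaths
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(nj > 1, (nj - dj) / (nj - 1), 0.0)
    w = dj / nj  # per-event-time death fraction

    best_key: tuple | None = None
    best_pair: tuple[float, float] | None = None
    for i in range(cand.size - 1):
        a = n_le[i]
        if a < min_n:
            continue
        if a > m - 2 * min_n:
            break
        jmask = (n_le - a >= min_n) & (m - n_le >= min_n) & (np.arange(cand.size) > i)
        js = np.flatnonzero(jmask)
        if js.size == 0:
            continue
        b = n_le[js]
        # group at-risk / death counts: (J,) for group 1, (J, nb) for group 2
        n1 = R[:, a]
        d1 = D[:, a]
        n2 = R[:, b] - n1[:, None]
        d2 = D[:, b] - d1[:, None]
        z1 = np.sum(d1 - w * n1)  # scalar
        z2 = np.sum(d2 - w[:, None] * n2, axis=0)  # (nb,)
        p1 = n1 / nj
        p2 = n2 / nj[:, None]
        dfr = dj * frac
        v11 = np.sum(dfr * p1 * (1.0 - p1))
        v22 = np.sum(dfr[:, None] * p2 * (1.0 - p2), axis=0)
        v12 = -np.sum(dfr[:, None] * p1[:, None] * p2, axis=0)
        det = v11 * v22 - v12 ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = (z1 ** 2 * v22 - 2.0 * z1 * z2 * v12 + z2 ** 2 * v11) / det
        stat = np.where(det > 0, np.maximum(stat, 0.0), 0.0)
        pvals = stats.chi2.sf(stat, 2)
        n_mid = b - a
        n_hi = m - b
        min_grp = np.minimum(a, np.minimum(n_mid, n_hi))
        for idx in range(js.size):
            key = (pvals[idx], -int(min_grp[idx]), cand[i], cand[js[idx]])
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (float(cand[i]), float(cand[js[idx]]))
    if best_pair is None:
        raise ValueError(
            f"no admissible threshold pair with min_fraction={min_fraction}; "
            "try a smaller min_fraction"
        )
    t_low, t_high = best_pair
    labels = np.where(awr <= t_low, 0, np.where(awr <= t_high, 1, 2))
    res = logrank_test(data, labels)
    return t_low, t_high, res


def assign_risk_class(awr: float, model: SwvgModel) -> RiskClass:
    """Classify one AWR value against the fitted thresholds.

    Boundary values belong to the lower class (awr == t_high is
    intermediate).
    """
    if awr <= model.t_low:
        return RiskClass.LOW
    if awr <= model.t_high:
        return RiskClass.INTERMEDIATE
    return RiskClass.HIGH


def risk_calls_matrix(models: tuple[DDgModel, ...], expression: pd.DataFrame) -> np.ndarray:
    """Binary vote matrix (patients x variables) for a variables-by-
    patients expression frame whose index matches the model ids."""
    calls = np.empty((expression.shape[1], len(models)), dtype=np.int8)
    for k, mdl in enumerate(models):
        if mdl.variable_id not in expression.index:
            raise KeyError(f"variable {mdl.variable_id!r} missing from expression matrix")
        vals = expression.loc[mdl.variable_id].to_numpy(dtype=float)
        above = vals > mdl.cutoff
        calls[:, k] = above if mdl.design == 2 else ~above
    return calls


def fit_swvg(
    expression: pd.DataFrame,
    data: SurvivalData,
    scheme: str = "C",
    *,
    min_fraction_ddg: float = 0.05,
    min_fraction_awr: float = 0.10,
    ties: str = "breslow",
) -> tuple[SwvgModel, np.ndarray, list[RiskClass]]:
    """End-to-end training: fit a 1D-DDg classifier per variable (rows of
    ``expression``), derive weights under ``scheme`` from the per-variable
    Wald p-values and hazard ratios, compute every patient's AWR and
    optimize the 3-group thresholds.

    Returns the fitted model, the per-patient AWR array (column order of
    ``expression``) and the per-patient training risk classes.
    """
    if expression.shape[1] != len(data):
        raise ValueError("expression columns must match the clinical cohort")
    models = tuple(
        fit_1d_ddg(
            expression.loc[vid].to_numpy(dtype=float),
            data,
            min_fraction_ddg,
            variable_id=str(vid),
            ties=ties,
        )
        for vid in expression.index
    )
    wv = compute_weights(
        np.array([m.wald_p for m in models]),
        np.array([m.hazard_ratio for m in models]),
        scheme,
        variable_ids=tuple(m.variable_id for m in models),
    )
    calls = risk_calls_matrix(models, expression)
    awr = calls @ wv.weights
    t_low, t_high, res = fit_awr_thresholds(awr, data, min_fraction_awr)
    model = SwvgModel(models, wv, t_low, t_high, res)
    classes = [assign_risk_class(a, model) for a in awr]
    return model, awr, classes
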