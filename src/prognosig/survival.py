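"""Foundational survival statistics.

Kaplan-Meier estimation, the k-sample log-rank test and a Cox
proportional-hazards fit for a single binary covariate (with Wald test).
These are the primitives every classification layer builds on: the
univariate cutoff scan refits the binary Cox model at every candidate
split, and the risk-score threshold search re-runs the 3-group log-rank
test for every admissible threshold pair, so both are implemented as
tight NumPy routines on pre-sorted arrays rather than through a
DataFrame-based survival interface.

Times are opaque positive reals (days by convention); events are 1 for
an observed death and 0 for censoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalData",
    "KMCurve",
    "CoxFit",
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "fit_binary_cox",
]

#: |beta| at which the Newton iteration is declared divergent
#: (complete separation of events between groups).
_BETA_CAP = 20.0


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival outcomes for a patient cohort.

    Parameters
    ----------
    times:
        Positive follow-up times, one per patient.
    events:
        1 if the death was observed at ``times[i]``, 0 if the patient
        was censored then.
    ids:
        Unique patient identifiers; generated as ``P0001..`` if omitted.
    """

    times: np.ndarray
    events: np.ndarray
    ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events)
        if times.ndim != 1 or times.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if times.shape != events.shape:
            raise ValueError("times and events must have equal length")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("survival times must be finite and > 0")
        ev = events.astype(float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            raise ValueError("events must be coded 0 (censored) or 1 (death)")
        ids = self.ids
        if not ids:
            ids = tuple(f"P{i + 1:04d}" for i in range(times.size))
        if len(ids) != times.size:
            raise ValueError("ids length must match times")
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", ev.astype(np.int8))
        object.__setattr__(self, "ids", tuple(ids))

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset(self, mask: np.ndarray) -> "SurvivalData":
        mask = np.asarray(mask, dtype=bool)
        ids = tuple(i for i, m in zip(self.ids, mask) if m)
        return SurvivalData(self.times[mask], self.events[mask], ids)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve evaluated at the distinct event times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


@dataclass(frozen=True)
class CoxFit:
    """Single binary covariate Cox fit: group 1 hazard relative to group 0."""

    beta: float
    se: float
    hazard_ratio: float
    wald_p: float
    n_iter: int = 0
    converged: bool = True
    separation: bool = False  # beta capped because the likelihood diverges


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    permutation_p: float | None = None


def km_estimate(data: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    Censored-only times contribute to the at-risk counts but create no
    step in the curve.
    """
    if data.n_events == 0:
        raise ValueError("no events observed: Kaplan-Meier curve undefined")
    order = np.argsort(data.times, kind="stable")
    times = data.times[order]
    events = data.events[order]
    n = times.size

    uniq, first_idx = np.unique(times, return_index=True)
    # at risk just before each distinct time
    at_risk_all = n - first_idx
    d = np.add.reduceat(events, first_idx)

    has_event = d > 0
    event_times = uniq[has_event]
    at_risk = at_risk_all[has_event]
    n_ev = d[has_event]
    surv = np.cumprod(1.0 - n_ev / at_risk)
    return KMCurve(event_times, surv, at_risk.astype(int), n_ev.astype(int))


def _group_counts(times: np.ndarray, events: np.ndarray, labels: np.ndarray, k: int):
    """Risk-set and death counts per group at each distinct event time.

    Returns (d_gj, n_gj) with shape (k, J): deaths and numbers at risk in
    group g at the j-th distinct event time.
    """
    order = np.argsort(times, kind="stable")
    times = times[order]
    events = events[order]
    labels = labels[order]

    event_times = np.unique(times[events == 1])
    J = event_times.size
    d = np.zeros((k, J))
    r = np.zeros((k, J))
    for g in range(k):
        m = labels == g
        tg = times[m]
        eg = events[m]
        # at risk in group g at time t_j: count of tg >= t_j
        r[g] = tg.size - np.searchsorted(np.sort(tg), event_times, side="left")
        te = tg[eg == 1]
        te_sorted = np.sort(te)
        d[g] = np.searchsorted(te_sorted, event_times, side="right") - np.searchsorted(
            te_sorted, event_times, side="left"
        )
    return event_times, d, r


def _logrank_statistic(times: np.ndarray, events: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Chi-square statistic of the k-sample log-rank test."""
    _, d, r = _group_counts(times, events, labels, k)
    dj = d.sum(axis=0)
    nj = r.sum(axis=0)
    # expected deaths and covariance of (O - E) over the first k-1 groups
    e = dj * r / nj
    z = (d - e).sum(axis=1)[: k - 1]

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(nj > 1, (nj - dj) / (nj - 1), 0.0)
    V = np.zeros((k - 1, k - 1))
    p = r / nj  # shape (k, J)
    for g in range(k - 1):
        for h in range(g, k - 1):
            delta = 1.0 if g == h else 0.0
            V[g, h] = V[h, g] = np.sum(dj * p[g] * (delta - p[h]) * frac)
    try:
        stat = float(z @ np.linalg.solve(V, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(V) @ z)
    return max(stat, 0.0)


def logrank_test(
    data: SurvivalData,
    group_labels: np.ndarray,
    *,
    n_permutations: int = 0,
    seed: int | None = None,
) -> LogRankResult:
    """k-sample log-rank test of equal hazard across groups.

    ``group_labels`` may use any k >= 2 distinct values; every group must
    be non-empty. The p-value is the chi-square upper tail with k-1
    degrees of freedom; with ``n_permutations`` > 0 a seeded
    label-permutation p-value is reported alongside (useful for tiny
    cohorts where the asymptotic is doubtful).
    """
    labels_raw = np.asarray(group_labels)
    if labels_raw.shape != data.times.shape:
        raise ValueError("group_labels length must match cohort size")
    uniq, labels = np.unique(labels_raw, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("log-rank test needs at least two groups")
    if data.n_events == 0:
        raise ValueError("no events observed: log-rank test undefined")

    stat = _logrank_statistic(data.times, data.events, labels, k)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))

    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            if _logrank_statistic(data.times, data.events, perm, k) >= stat - 1e-12:
                count += 1
        perm_p = (count + 1) / (n_permutations + 1)
    return LogRankResult(stat, df, max(p, np.finfo(float).tiny), perm_p)


def _cox_prepare(times: np.ndarray, events: np.ndarray, group: np.ndarray):
    """Per-event-time sufficient statistics for the binary-covariate
    partial likelihood: deaths (total / group-1) and at-risk counts
    (total / group-1) at each distinct event time."""
    event_times, d, r = _group_counts(times, events, group.astype(int), 2)
    return d[1], d.sum(axis=0), r[1], r.sum(axis=0)


def _cox_score_info(beta, d1, dj, r1, rj, ties="breslow"):
    """Score U(beta) and observed information I(beta).

    Breslow: all d_j tied deaths at t_j share the full risk set.
    Efron: the l-th of d_j tied deaths sees the risk sum reduced by
    (l/d_j) of the tied-death sum.
    """
    eb = np.exp(beta)
    if ties == "breslow":
        s1 = r1 * eb
        s0 = (rj - r1) + s1
        mu = s1 / s0
        U = float(np.sum(d1 - dj * mu))
        I = float(np.sum(dj * mu * (1.0 - mu)))
        ll = float(np.sum(d1 * beta - dj * np.log(s0)))
        return U, I, ll
    # Efron
    U = 0.0
    I = 0.0
    ll = 0.0
    for j in range(dj.size):
        dj_j = int(dj[j])
        if dj_j == 0:
            continue
        S1 = r1[j] * eb
        S0 = (rj[j] - r1[j]) + S1
        t1 = d1[j] * eb
        t0 = (dj_j - d1[j]) + t1
        ll += d1[j] * beta
        for l in range(dj_j):
            f = l / dj_j
            s0 = S0 - f * t0
            s1 = S1 - f * t1
            mu = s1 / s0
            U += (d1[j] / dj_j) - mu
            I += mu * (1.0 - mu)
            ll -= np.log(s0)
    return float(U), float(I), float(ll)


def fit_binary_cox(
    data: SurvivalData,
    group: np.ndarray,
    *,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Cox proportional-hazards fit for one binary covariate.

    Maximizes the partial likelihood by Newton-Raphson from beta = 0
    with Breslow tie handling (``ties="efron"`` for the Efron
    correction). The Wald p-value is 2(1 - Phi(|beta|/se)).

    Under complete separation of events the likelihood is maximized at
    beta = +/-inf; the estimate is then capped and ``separation`` set.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie handling: {ties!r}")
    group = np.asarray(group)
    if group.shape != data.times.shape:
        raise ValueError("group length must match cohort size")
    gvals = np.unique(group)
    if not np.all(np.isin(gvals, (0, 1))):
        raise ValueError("group must be coded 0/1")
    if gvals.size < 2:
        raise ValueError("both groups must be non-empty")
    if data.n_events == 0:
        raise ValueError("no events observed: Cox fit undefined")

    d1, dj, r1, rj = _cox_prepare(data.times, data.events, group.astype(int))

    beta = 0.0
    separation = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U, I, _ = _cox_score_info(beta, d1, dj, r1, rj, ties)
        if I <= 0:
            separation = True
            break
        step = U / I
        # dampen absurd steps far from the optimum
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(beta) > _BETA_CAP:
            separation = True
            beta = float(np.sign(beta) * _BETA_CAP)
            break
        if abs(step) < tol:
            converged = True
            break

    _, I, _ = _cox_score_info(beta, d1, dj, r1, rj, ties)
    if separation or I <= 0:
        separation = True
        warnings.warn(
            "complete separation in binary Cox fit: beta capped at "
            f"{beta:+.1f}; Wald p unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
        se = float("inf") if I <= 0 else float(1.0 / np.sqrt(I))
    else:
        se = float(1.0 / np.sqrt(I))
    z = abs(beta) / se if np.isfinite(se) and se > 0 else 0.0
    wald_p = float(2.0 * stats.norm.sf(z))
    return CoxFit(
        beta=float(beta),
        se=se,
        hazard_ratio=float(np.exp(beta)),
        wald_p=max(wald_p, np.finfo(float).tiny),
        n_iter=it,
        converged=converged,
        separation=separation,
    )


def cox_partial_loglik(
    data: SurvivalData, group: np.ndarray, beta: float, *, ties: str = "breslow"
) -> float:
    """Partial log-likelihood at a given beta (exposed for oracle checks)."""
    d1, dj, r1, rj = _cox_prepare(data.times, data.events, np.asarray(group).astype(int))
    _, _, ll = _cox_score_info(float(beta), d1, dj, r1, rj, ties)
    return ll
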