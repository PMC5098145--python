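"""Prognostic Signature Vector Matching (PSVM).

Personalized risk prediction by nearest-reference matching. Each
patient's binary risk votes form a prognostic binary variable vector
(PBVV); ranking the signature variables by descending weight and
replacing each set bit by its reverse rank (most important variable ->
n, least -> 1) yields the prognostic signature vector (PSV). A query
patient receives the risk class of the Euclidean-nearest reference
patient in PSV space. PSVs are used un-scaled: the rank magnitudes are
the point, encoding that disagreement on an important variable moves a
patient further than disagreement on a marginal one.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np

from .ddg import DDgModel, apply_1d_ddg
from .swvg import RiskClass, SwvgModel
from .weights import WeightVector

__all__ = [
    "PBVV",
    "PSV",
    "MatchResult",
    "build_pbvv",
    "pbvv_to_psv",
    "rank_scores",
    "match_nearest",
    "predict_psvm",
]


@dataclass(frozen=True)
class PBVV:
    """Per-patient binary risk-vote vector, aligned to the signature order."""

    patient_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if not np.all(np.isin(bits, (0, 1))):
            raise ValueError("PBVV bits must be 0/1")
        object.__setattr__(self, "bits", bits.astype(np.int8))


@dataclass(frozen=True)
class PSV:
    """Rank-weighted signature vector; component i is 0 where bit i is 0."""

    patient_id: str
    components: np.ndarray
    un_scaled: bool = True

    def __post_init__(self) -> None:
        comp = np.asarray(self.components, dtype=float)
        if not np.all(np.isfinite(comp)) or np.any(comp < 0):
            raise ValueError("PSV components must be finite and non-negative")
        object.__setattr__(self, "components", comp)


@dataclass(frozen=True)
class MatchResult:
    query_id: str
    reference_id: str
    distance: float
    predicted_class: RiskClass


def build_pbvv(
    models: tuple[DDgModel, ...],
    patient_values: np.ndarray,
    patient_id: str = "query",
    *,
    impute: np.ndarray | None = None,
) -> PBVV:
    """Apply each fitted cutoff classifier to the patient's values.

    Missing (NaN) values raise by default; pass ``impute`` (e.g. the
    training cohort per-variable medians) to substitute them instead.
    """
    vals = np.asarray(patient_values, dtype=float)
    if vals.size != len(models):
        raise ValueError("patient values must align with the signature models")
    missing = ~np.isfinite(vals)
    if missing.any():
        if impute is None:
            bad = [models[i].variable_id for i in np.flatnonzero(missing)]
            raise ValueError(f"missing values for variables {bad}; supply impute=")
        vals = np.where(missing, np.asarray(impute, dtype=float), vals)
    bits = np.array([apply_1d_ddg(m, v) for m, v in zip(models, vals)], dtype=np.int8)
    return PBVV(patient_id=patient_id, bits=bits)


def rank_scores(w: WeightVector) -> np.ndarray:
    """Reverse-rank score per variable: the heaviest variable scores n,
    the lightest scores 1. Ties in weight are broken by signature order
    (earlier variable ranks higher), keeping the transform deterministic
    under the constant scheme."""
    n = len(w)
    # stable argsort of descending weight = weight rank with order tie-break
    order = np.argsort(-w.weights, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return (n - ranks + 1).astype(float)


def pbvv_to_psv(pbvv: PBVV, w: WeightVector, *, use_weights: bool = False) -> PSV:
    """Convert the binary vector to a prognostic signature vector.

    Default (rank transform): component_i = bits_i * (n - r_i + 1) with
    r_i the descending-weight rank. ``use_weights=True`` substitutes the
    raw weight for the rank score (sensitivity-analysis variant).
    """
    if pbvv.bits.size != len(w):
        raise ValueError("PBVV must align with the weight vector")
    scores = w.weights if use_weights else rank_scores(w)
    return PSV(patient_id=pbvv.patient_id, components=pbvv.bits * scores, un_scaled=True)


def match_nearest(query: PSV, references: list[PSV], reference_classes: list[RiskClass]) -> MatchResult:
    """Euclidean nearest reference in PSV space.

    Distance ties: the majority risk class among all tied references;
    a residual tie goes to the lowest-risk class. The reported reference
    is the first tied one in input order.
    """
    if not references:
        raise ValueError("reference set is empty")
    if len(references) != len(reference_classes):
        raise ValueError("reference classes must align with reference PSVs")
    ref_matrix = np.vstack([r.components for r in references])
    if ref_matrix.shape[1] != query.components.size:
        raise ValueError("query and reference PSVs must have equal length")
    d2 = np.sum((ref_matrix - query.components) ** 2, axis=1)
    dmin = d2.min()
    tied = np.flatnonzero(np.isclose(d2, dmin, rtol=0.0, atol=1e-12))
    if tied.size == 1:
        best = tied[0]
        cls = reference_classes[best]
    else:
        votes = Counter(reference_classes[i] for i in tied)
        top = max(votes.values())
        cls = min(c for c, v in votes.items() if v == top)  # residual tie -> lowest risk
        best = tied[0]
    return MatchResult(
        query_id=query.patient_id,
        reference_id=references[best].patient_id,
        distance=float(np.sqrt(dmin)),
        predicted_class=cls,
    )


def build_reference_psvs(
    model: SwvgModel,
    expression,
    ids: tuple[str, ...] | None = None,
) -> list[PSV]:
    """Reference PSVs for a variables-by-patients expression frame."""
    from .swvg import risk_calls_matrix

    calls = risk_calls_matrix(model.ddg_models, expression)
    scores = rank_scores(model.weight_vector)
    pid = ids or tuple(map(str, expression.columns))
    return [PSV(patient_id=pid[i], components=calls[i] * scores) for i in range(calls.shape[0])]


def predict_psvm(
    query_values: np.ndarray,
    model: SwvgModel,
    references: list[PSV],
    reference_classes: list[RiskClass],
    query_id: str = "query",
) -> MatchResult:
    """Full personalized prediction: PBVV -> PSV -> nearest reference ->
    that reference's risk class."""
    pbvv = build_pbvv(model.ddg_models, query_values, patient_id=query_id)
    psv = pbvv_to_psv(pbvv, model.weight_vector)
    return match_nearest(psv, references, reference_classes)
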