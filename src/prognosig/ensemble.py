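"""Multi-classifier voting ensemble.

Six classical learners (KNN, SVM with RBF and linear kernels, random
forest, one-hidden-layer neural network, logistic regression) are
trained one-vs-rest on *scaled* signature vectors with the risk classes
from the weighted-voting stratification as labels, under stratified
10-fold cross-validation. A test patient's prediction from one learner
is the consensus of its ten fold-models; the ensemble's final call is
the majority among the seven methods (the six learners plus the
nearest-reference matcher, which by design consumes un-scaled vectors).
Goodman-Kruskal gamma quantifies the ordinal concordance between any
two methods' outputs.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .swvg import RiskClass

__all__ = [
    "LEARNERS",
    "METHODS",
    "ScaledFeatures",
    "FoldAssignment",
    "scale_features",
    "stratified_folds",
    "make_learner",
    "train_ovr",
    "consensus_predict",
    "majority_vote",
    "gamma_correlation",
    "gamma_matrix",
    "EnsembleResult",
    "run_ensemble",
]

LEARNERS = ("knn", "svm_rbf", "svm_linear", "rf", "nn", "lr")
#: the seven voting methods, in reporting order
METHODS = ("psvm",) + LEARNERS

#: default hyperparameters; every value can be overridden per learner
DEFAULT_HYPERPARAMS: dict[str, dict[str, Any]] = {
    "knn": {"n_neighbors": 5},
    "svm_rbf": {"C": 1.0, "gamma": "auto"},  # gamma = 1 / n_features
    "svm_linear": {"C": 1.0},
    "rf": {"n_estimators": 100},
    "nn": {"hidden_layer_sizes": (32,), "max_iter": 2000},
    "lr": {"C": 1.0, "max_iter": 1000},  # ridge (L2) penalized, sklearn default
}


@dataclass(frozen=True)
class ScaledFeatures:
    """Train/test matrices standardized with training statistics only."""

    train: np.ndarray
    test: np.ndarray | None
    center: np.ndarray
    scale: np.ndarray


@dataclass(frozen=True)
class FoldAssignment:
    fold_id: np.ndarray  # values in 1..k
    k: int
    seed: int


def scale_features(train: np.ndarray, test: np.ndarray | None = None) -> ScaledFeatures:
    """z = (x - mean_train) / sd_train with the population sd (divide by
    n); test rows are transformed with the training statistics. A
    zero-variance training feature is left centered with scale 1 (and a
    warning) rather than producing NaNs."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("need a 2-D training matrix with >= 2 rows")
    scaler = StandardScaler()  # population (ddof=0) sd, constant columns -> scale 1
    train_z = scaler.fit_transform(train)
    if np.any(scaler.var_ == 0):
        warnings.warn(
            f"{int(np.sum(scaler.var_ == 0))} zero-variance training feature(s): scale fixed at 1",
            RuntimeWarning,
            stacklevel=2,
        )
    test_z = scaler.transform(np.asarray(test, dtype=float)) if test is not None else None
    return ScaledFeatures(train=train_z, test=test_z, center=scaler.mean_.copy(), scale=scaler.scale_.copy())


def stratified_folds(labels: Sequence, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified fold assignment: seeded shuffle within each class, then
    round-robin over the folds with a carried starting position so that
    both the per-fold class counts and the fold totals stay within one
    patient of perfectly proportional."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold_id = np.zeros(labels.size, dtype=int)
    pointer = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls!r} has {idx.size} members, fewer than k={k} folds")
        idx = rng.permutation(idx)
        folds = (pointer + np.arange(idx.size)) % k
        fold_id[idx] = folds + 1
        pointer = (pointer + idx.size) % k
    return FoldAssignment(fold_id=fold_id, k=k, seed=seed)


def make_learner(learner_spec: str, seed: int | None = None, hyperparams: Mapping[str, Any] | None = None):
    """Instantiate a one-vs-rest classifier for one of the named learners."""
    if learner_spec not in LEARNERS:
        raise ValueError(f"unknown learner {learner_spec!r}; choose from {LEARNERS}")
    params = dict(DEFAULT_HYPERPARAMS[learner_spec])
    if hyperparams:
        params.update(hyperparams)
    if learner_spec == "knn":
        base = KNeighborsClassifier(**params)
    elif learner_spec == "svm_rbf":
        base = SVC(kernel="rbf", **params)
    elif learner_spec == "svm_linear":
        base = SVC(kernel="linear", **params)
    elif learner_spec == "rf":
        base = RandomForestClassifier(random_state=seed, **params)
    elif learner_spec == "nn":
        base = MLPClassifier(random_state=seed, **params)
    else:
        base = LogisticRegression(**params)
    return OneVsRestClassifier(base)


def train_ovr(
    features: np.ndarray,
    labels: Sequence,
    learner_spec: str,
    *,
    seed: int | None = None,
    hyperparams: Mapping[str, Any] | None = None,
):
    """Fit one binary classifier per class against the rest; prediction is
    the class with the maximal decision score."""
    y = np.asarray([int(v) for v in labels])
    if np.unique(y).size < 2:
        raise ValueError("labels are single-class: one-vs-rest training is degenerate")
    clf = make_learner(learner_spec, seed=seed, hyperparams=hyperparams)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")
        clf.fit(np.asarray(features, dtype=float), y)
    return clf


def consensus_predict(
    fold_models: Sequence, query: np.ndarray, train_prevalence: Mapping[RiskClass, int]
) -> list[RiskClass]:
    """Majority class over the fold-model predictions for each query row.

    A vote tie goes to the class with the larger training prevalence;
    a residual tie goes to the lower risk class.
    """
    query = np.atleast_2d(np.asarray(query, dtype=float))
    votes = np.stack([np.asarray(m.predict(query)) for m in fold_models])  # (folds, rows)
    out: list[RiskClass] = []
    for j in range(votes.shape[1]):
        tally = Counter(int(v) for v in votes[:, j])
        top = max(tally.values())
        tied = [RiskClass(c) for c, n in tally.items() if n == top]
        tied.sort(key=lambda c: (-train_prevalence.get(c, 0), int(c)))
        out.append(tied[0])
    return out


def majority_vote(method_predictions: Mapping[str, RiskClass]) -> RiskClass:
    """Final ensemble call: the modal class among the seven methods.

    A tie between modal classes is resolved by the nearest-reference
    matcher's own prediction when it is among them, else the lowest-risk
    tied class.
    """
    missing = [m for m in METHODS if m not in method_predictions]
    if missing:
        raise ValueError(f"missing method predictions: {missing}")
    preds = {m: method_predictions[m] for m in METHODS}
    tally = Counter(preds.values())
    top = max(tally.values())
    tied = sorted(c for c, n in tally.items() if n == top)
    if len(tied) == 1:
        return tied[0]
    if preds["psvm"] in tied:
        return preds["psvm"]
    return tied[0]


def gamma_correlation(x: Sequence, y: Sequence) -> float | None:
    """Goodman-Kruskal gamma: (C - D) / (C + D) over all pairs, with C
    concordant and D discordant pairs; ties contribute to neither. When
    every pair is tied the coefficient is undefined and None is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D sequences of length >= 2")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    c = int(np.sum(prod > 0) // 2)
    d = int(np.sum(prod < 0) // 2)
    if c + d == 0:
        return None
    return (c - d) / (c + d)


def gamma_matrix(columns: pd.DataFrame) -> pd.DataFrame:
    """Pairwise gamma between ordinal columns (None where undefined)."""
    names = list(columns.columns)
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            g = gamma_correlation(columns[a].to_numpy(), columns[b].to_numpy())
            out.loc[a, b] = out.loc[b, a] = np.nan if g is None else g
    return out


@dataclass
class EnsembleResult:
    """Everything the voting ensemble produces on a test cohort."""

    test_predictions: pd.DataFrame  # one column per method + "overall"
    cv_accuracy: dict[str, float]
    fold_assignment: FoldAssignment
    gamma: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_ensemble(
    train_features: np.ndarray,
    train_labels: Sequence[RiskClass],
    test_features: np.ndarray,
    psvm_test_predictions: Sequence[RiskClass],
    *,
    k: int = 10,
    seed: int = 0,
    learners: Sequence[str] = LEARNERS,
    hyperparams: Mapping[str, Mapping[str, Any]] | None = None,
    test_ids: Sequence[str] | None = None,
) -> EnsembleResult:
    """Train the six learners with stratified k-fold CV on scaled
    features, predict the test cohort by fold consensus, combine with
    the matcher's predictions and take the 7-method majority vote.

    ``train_features``/``test_features`` are patients-by-variables
    signature-vector matrices (un-scaled; scaling with training
    statistics happens internally for the learners only).
    """
    train_labels = [RiskClass(int(c)) for c in train_labels]
    scaled = scale_features(train_features, test_features)
    folds = stratified_folds([int(c) for c in train_labels], k=k, seed=seed)
    prevalence = Counter(train_labels)
    y = np.asarray([int(c) for c in train_labels])

    preds: dict[str, list[RiskClass]] = {"psvm": [RiskClass(int(c)) for c in psvm_test_predictions]}
    cv_acc: dict[str, float] = {}
    for li, spec in enumerate(learners):
        hp = (hyperparams or {}).get(spec)
        fold_models = []
        correct = 0
        for f in range(1, k + 1):
            val = folds.fold_id == f
            mdl = train_ovr(
                scaled.train[~val], y[~val], spec, seed=seed + 1000 * (li + 1) + f, hyperparams=hp
            )
            fold_models.append(mdl)
            correct += int(np.sum(mdl.predict(scaled.train[val]) == y[val]))
        cv_acc[spec] = correct / y.size
        preds[spec] = consensus_predict(fold_models, scaled.test, prevalence)

    n_test = len(preds["psvm"])
    for spec in learners:
        if len(preds[spec]) != n_test:
            raise ValueError("prediction length mismatch across methods")
    overall = [
        majority_vote({m: preds[m][j] for m in ("psvm",) + tuple(learners)}) for j in range(n_test)
    ]
    ids = list(test_ids) if test_ids is not None else [f"T{j + 1:04d}" for j in range(n_test)]
    table = pd.DataFrame(
        {m: [int(c) for c in preds[m]] for m in ("psvm",) + tuple(learners)}, index=ids
    )
    table["overall"] = [int(c) for c in overall]
    gam = gamma_matrix(table)
    return EnsembleResult(test_predictions=table, cv_accuracy=cv_acc, fold_assignment=folds, gamma=gam)
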