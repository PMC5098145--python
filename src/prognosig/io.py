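"""Readers, writers and model persistence.

Canonical dialect is tab-separated UTF-8 with '.' decimals (CSV is
accepted on read by sniffing the delimiter). Expression matrices are
variables-by-patients with variable ids in the first column and patient
ids in the header; clinical tables carry patient_id / time / event
(0/1) and optional covariate columns. Patient order is preserved
everywhere, never silently sorted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ddg import DDgModel
from .survival import LogRankResult, SurvivalData
from .swvg import RiskClass, SwvgModel
from .weights import WeightVector

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_signature_table",
    "write_signature_table",
    "signature_to_models",
    "models_to_signature",
    "save_swvg_model",
    "load_swvg_model",
    "write_risk_report",
]

logger = logging.getLogger("prognosig")

SIGNATURE_COLUMNS = [
    "variable",
    "description",
    "wald_p",
    "cutoff",
    "design",
    "behaviour",
    "hazard_ratio",
    "n_low_risk",
    "n_high_risk",
]

_MODEL_FORMAT_VERSION = 1


def _float_repr(v) -> str:
    """Shortest round-tripping decimal form (exact read-back)."""
    return repr(float(v))


def _sep(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a variables-by-patients numeric matrix (TSV, or CSV by
    extension). Duplicate variable or patient ids and non-numeric cells
    are rejected with the offending row/column named."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate variable id(s) in {path.name}: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate patient id(s) in {path.name}: {dup}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-numeric cell in {path.name} at row {row!r}, column {col!r}")
        df[col] = coerced
    df.columns = df.columns.map(str)
    df.index = df.index.map(str)
    df.index.name = None
    return df.astype(float)


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep(path), index_label="variable", float_format=_float_repr)


def read_clinical_table(
    path: str | Path, expression: pd.DataFrame | None = None
) -> tuple[SurvivalData, pd.DataFrame]:
    """Read patient_id / time / event (plus optional covariates).

    When an expression matrix is given, patients are intersected with
    its columns (expression order kept); mismatches are logged and
    dropped. Returns the survival data and the covariate frame
    (patient-indexed, possibly empty).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
    required = {"patient_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical table {path.name} must have columns {sorted(required)}")
    df["patient_id"] = df["patient_id"].map(str)
    if df["patient_id"].duplicated().any():
        raise ValueError(f"duplicate patient_id in {path.name}")
    times = pd.to_numeric(df["time"], errors="raise").to_numpy(dtype=float)
    events = pd.to_numeric(df["event"], errors="raise").to_numpy()
    if np.any(times <= 0):
        raise ValueError(f"non-positive survival time in {path.name}")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError(f"event values outside {{0,1}} in {path.name}")
    if expression is not None:
        keep = df["patient_id"].isin(expression.columns)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning(
                "%d patient(s) in clinical table but not expression matrix: excluded", n_drop
            )
        order = {pid: k for k, pid in enumerate(expression.columns)}
        df = df[keep].sort_values("patient_id", key=lambda s: s.map(order)).reset_index(drop=True)
        times = df["time"].to_numpy(dtype=float)
        events = df["event"].to_numpy()
    data = SurvivalData(times=times, events=events.astype(int), ids=tuple(df["patient_id"]))
    covariates = df.drop(columns=["time", "event"]).set_index("patient_id")
    return data, covariates


def write_clinical_table(data: SurvivalData, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"patient_id": list(data.ids), "time": data.times, "event": data.events}
    ).to_csv(path, sep=_sep(path), index=False, float_format=_float_repr)


def read_signature_table(path: str | Path) -> pd.DataFrame:
    """Read a fitted-signature table (variable, cutoff, design, Wald p,
    hazard ratio, subgroup counts)."""
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sep(path), float_precision="round_trip",
        dtype={"variable": str, "description": str, "behaviour": str},
    )
    missing = [c for c in SIGNATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"signature table {path.name} missing columns {missing}")
    df = df[SIGNATURE_COLUMNS]
    if df["variable"].duplicated().any():
        raise ValueError(f"duplicate variable in signature table {path.name}")
    if not df["design"].isin((1, 2)).all():
        raise ValueError("design must be 1 or 2")
    return df


def write_signature_table(df: pd.DataFrame, path: str | Path) -> None:
    df[SIGNATURE_COLUMNS].to_csv(Path(path), sep="\t", index=False, float_format=_float_repr)


def signature_to_models(df: pd.DataFrame) -> tuple[DDgModel, ...]:
    return tuple(
        DDgModel(
            variable_id=str(r.variable),
            cutoff=float(r.cutoff),
            design=int(r.design),
            wald_p=float(r.wald_p),
            hazard_ratio=float(r.hazard_ratio),
            n_low_risk=int(r.n_low_risk),
            n_high_risk=int(r.n_high_risk),
            description="" if pd.isna(r.description) else str(r.description),
        )
        for r in df.itertuples()
    )


def models_to_signature(models: tuple[DDgModel, ...]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": m.variable_id,
                "description": m.description,
                "wald_p": m.wald_p,
                "cutoff": m.cutoff,
                "design": m.design,
                "behaviour": m.behaviour,
                "hazard_ratio": m.hazard_ratio,
                "n_low_risk": m.n_low_risk,
                "n_high_risk": m.n_high_risk,
            }
            for m in models
        ],
        columns=SIGNATURE_COLUMNS,
    )


def save_swvg_model(model: SwvgModel, path: str | Path) -> None:
    """Persist a fitted stratifier as versioned JSON."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "ddg_models": [dataclasses.asdict(m) for m in model.ddg_models],
        "weights": {
            "scheme": model.weight_vector.scheme,
            "variable_ids": list(model.weight_vector.variable_ids),
            "weights": model.weight_vector.weights.tolist(),
        },
        "t_low": model.t_low,
        "t_high": model.t_high,
        "training_logrank": {
            "statistic": model.training_logrank.statistic,
            "df": model.training_logrank.df,
            "p_value": model.training_logrank.p_value,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_swvg_model(path: str | Path) -> SwvgModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {payload.get('format_version')}")
    models = tuple(DDgModel(**m) for m in payload["ddg_models"])
    wv = WeightVector(
        scheme=payload["weights"]["scheme"],
        variable_ids=tuple(payload["weights"]["variable_ids"]),
        weights=np.asarray(payload["weights"]["weights"], dtype=float),
    )
    lr = LogRankResult(**payload["training_logrank"])
    return SwvgModel(models, wv, payload["t_low"], payload["t_high"], lr)


def write_risk_report(
    assignments: pd.DataFrame,
    data: SurvivalData,
    out_dir: str | Path,
    *,
    group_column: str = "risk_class",
    plot: bool = True,
) -> dict:
    """Write the per-patient predictions TSV, a Kaplan-Meier plot per
    grouping column, and a stats JSON with the log-rank test of the
    grouping. ``assignments`` is patient-indexed (input order) and must
    contain ``group_column`` with risk-class labels."""
    from .survival import km_estimate, logrank_test

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assignments.to_csv(out_dir / "predictions.tsv", sep="\t", index_label="patient_id")

    labels = assignments[group_column].map(
        lambda v: int(RiskClass.from_label(v)) if isinstance(v, str) else int(v)
    )
    res = logrank_test(data, labels.to_numpy())
    stats = {
        "n_patients": len(data),
        "n_events": data.n_events,
        "logrank_statistic": res.statistic,
        "logrank_df": res.df,
        "logrank_p": res.p_value,
        "group_sizes": {str(RiskClass(int(g))): int(n) for g, n in labels.value_counts().items()},
    }
    (out_dir / "stats.json").write_text(json.dumps(stats, indent=1), encoding="utf-8")

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        for g in sorted(labels.unique()):
            sub = data.subset(labels.to_numpy() == g)
            if sub.n_events == 0:
                continue
            curve = km_estimate(sub)
            t = np.concatenate([[0.0], np.repeat(curve.event_times, 2)])
            s = np.concatenate([[1.0, 1.0], np.repeat(curve.survival_probs, 2)[:-1]])
            ax.plot(t, s, label=f"{RiskClass(int(g))} (n={len(sub)})")
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        ax.set_title(f"log-rank p = {res.p_value:.3g}")
        fig.tight_layout()
        fig.savefig(out_dir / f"km_{group_column}.png", dpi=120)
        plt.close(fig)
    logger.info(
        "risk report: n=%d, events=%d, log-rank p=%.3g -> %s",
        len(data), data.n_events, res.p_value, out_dir,
    )
    return stats
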