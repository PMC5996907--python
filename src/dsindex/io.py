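"""Cohort CSV readers/writers, model persistence and run manifests.

The cohort lives in one wide CSV: ``subject_id``, ``diagnosis``, the four
nuisance covariates (``age``, ``sex``, ``education``, ``scanner``) and one
column per feature.  Empty cells are missing values, never zeros; numeric
parsing is locale-independent (dot decimal separator).

Fitted classifiers serialize to JSON — fitness models are just sorted value
lists plus weights — so saved models are plain text and diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import DSIClassifier
from .config import COVARIATE_COLS, ID_COL, LABEL_COL, StudyConfig
from .evaluation import RejectionCurve
from .preprocessing import NuisanceNormalizer

logger = logging.getLogger(__name__)


class CohortLoadError(ValueError):
    """Malformed cohort file, with row/column context in the message."""


def read_cohort(path: str | Path, config: StudyConfig) -> pd.DataFrame:
    """Read and validate a cohort CSV against the study configuration."""
    table = pd.read_csv(path, dtype={ID_COL: str, LABEL_COL: str, "sex": str,
                                     "scanner": str},
                        float_precision="round_trip")
    expected = {ID_COL, LABEL_COL, *COVARIATE_COLS, *config.feature_names}
    unknown = [c for c in table.columns if c not in expected]
    if unknown:
        raise CohortLoadError(f"{path}: unknown columns {unknown}")
    missing_cols = [c for c in (ID_COL, LABEL_COL) if c not in table.columns]
    if missing_cols:
        raise CohortLoadError(f"{path}: required columns missing: {missing_cols}")
    if table[ID_COL].duplicated().any():
        dupes = table.loc[table[ID_COL].duplicated(), ID_COL].tolist()
        raise CohortLoadError(f"{path}: duplicate subject ids {dupes[:5]}")

    bad = ~table[LABEL_COL].isin(config.classes)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise CohortLoadError(
            f"{path}: row {row + 2}: unknown diagnosis {table.loc[row, LABEL_COL]!r} "
            f"(expected one of {config.classes})"
        )
    for col in config.feature_names:
        if col not in table.columns:
            continue
        try:
            table[col] = pd.to_numeric(table[col])
        except (ValueError, TypeError) as exc:
            raise CohortLoadError(f"{path}: column {col!r}: non-numeric value ({exc})") from exc
    return table


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    # 17 significant digits round-trip IEEE doubles, keeping the file bit-exact
    cohort.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# model persistence (JSON, text-only)
# ---------------------------------------------------------------------------

def save_model(model: DSIClassifier, path: str | Path,
               normalizer: "NuisanceNormalizer | None" = None) -> None:
    """Write a fitted classifier (and optionally its fitted nuisance
    normalizer, so predictions on new data use training-cohort statistics)."""
    payload = {"format": "dsindex-model", "version": __version__, "model": model.to_dict()}
    if normalizer is not None:
        payload["normalizer"] = normalizer.to_dict()
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[DSIClassifier, "NuisanceNormalizer | None"]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "dsindex-model":
        raise ValueError(f"{path} is not a dsindex model file")
    normalizer = None
    if "normalizer" in payload:
        normalizer = NuisanceNormalizer.from_dict(payload["normalizer"])
    return DSIClassifier.from_dict(payload["model"]), normalizer


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _fmt_pct(value) -> str:
    """Percent with one decimal; undefined values render as N/A."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "N/A"
    return f"{value:.1f}"


def write_report(predictions: pd.DataFrame, metrics: dict | None,
                 curve: RejectionCurve | None, out_dir: str | Path,
                 branch_scores: pd.DataFrame | None = None) -> list[Path]:
    """Write predictions/metrics/rejection CSVs plus a per-subject summary.

    The plain-text summary lists, for each subject, the predicted class, the
    confidence, every class total index and — when ``branch_scores`` is given —
    each modality branch's composite contribution (text analogue of the
    per-subject fingerprint view of the decision support tool).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    pred_path = out_dir / "predictions.csv"
    predictions.to_csv(pred_path, index=False)
    written.append(pred_path)

    if metrics is not None:
        rows = [{"metric": "accuracy", "value_pct": _fmt_pct(metrics["accuracy"])},
                {"metric": "balanced_accuracy",
                 "value_pct": _fmt_pct(metrics["balanced_accuracy"])}]
        for c, s in metrics["sensitivities"].items():
            rows.append({"metric": f"sensitivity_{c}", "value_pct": _fmt_pct(s)})
        metrics_path = out_dir / "metrics.csv"
        pd.DataFrame(rows).to_csv(metrics_path, index=False)
        written.append(metrics_path)
        cm_path = out_dir / "confusion_matrix.csv"
        metrics["confusion"].to_frame().to_csv(cm_path)
        written.append(cm_path)

    if curve is not None:
        curve_path = out_dir / "rejection_curve.csv"
        frame = curve.to_frame()
        frame["balanced_accuracy"] = [
            _fmt_pct(v) for v in frame["balanced_accuracy"]
        ]
        frame.to_csv(curve_path, index=False)
        written.append(curve_path)

    summary_path = out_dir / "subject_summaries.txt"
    dsi_cols = [c for c in predictions.columns if c.startswith("dsi_")]
    with open(summary_path, "w") as fh:
        for _, row in predictions.iterrows():
            fh.write(f"subject {row['subject_id']}\n")
            fh.write(f"  predicted: {row['predicted']}  confidence: {row['confidence']:.3f}")
            if row.get("flag_no_features", False):
                fh.write("  [no usable features]")
            fh.write("\n")
            for col in dsi_cols:
                fh.write(f"  total index {col[4:]}: {row[col]:.3f}\n")
            if branch_scores is not None and row["subject_id"] in branch_scores.index:
                for branch, score in branch_scores.loc[row["subject_id"]].items():
                    rendered = "missing" if pd.isna(score) else f"{score:.3f}"
                    fh.write(f"  branch {branch}: {rendered}\n")
            fh.write("\n")
    written.append(summary_path)
    return written


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def write_manifest(out_dir: str | Path, command: str, seed: int | None,
                   config_path: str | Path | None, inputs: list[str],
                   outputs: list[str]) -> Path:
    """One JSON manifest per CLI run: enough to reproduce the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = None
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    manifest = {
        "command": command,
        "seed": seed,
        "config": str(config_path) if config_path else None,
        "config_sha256": digest,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
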