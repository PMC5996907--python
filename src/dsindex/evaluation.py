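"""Cross-validated evaluation, confusion-matrix metrics and rejection curves.

Performance is summarized by the accuracy (fraction of correctly classified
subjects) and the balanced accuracy (mean of per-class sensitivities), both
in percent.  Balanced accuracy equals 100/K for a random guesser over K
classes and is undefined once any class has no evaluated subjects.

The confidence measure of the classifier — the maximum total index — supports
classification with a reject option: subjects the classifier is least
confident about are excluded and the metrics recomputed on the retained
subset, trading coverage for accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold

from .classifier import DSIClassifier
from .config import COVARIATE_COLS, ID_COL, LABEL_COL, StudyConfig
from .hierarchy import MODALITIES
from .preprocessing import NuisanceNormalizer


@dataclass
class ConfusionMatrix:
    """K x K counts with rows = true class, columns = predicted class."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes: list[str]) -> "ConfusionMatrix":
        counts = skmetrics.confusion_matrix(y_true, y_pred, labels=classes)
        return cls(list(classes), counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent of correctly classified subjects: 100 * trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def sensitivities(cm: ConfusionMatrix) -> dict[str, float]:
    """Per-class sensitivity in percent (NaN for classes with no subjects)."""
    rows = cm.row_sums()
    diag = np.diag(cm.counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(rows > 0, 100.0 * diag / np.where(rows > 0, rows, 1), np.nan)
    return dict(zip(cm.classes, sens.astype(float)))


def balanced_accuracy(cm: ConfusionMatrix) -> float | None:
    """Mean of per-class sensitivities in percent.

    Undefined (None) when any class has no evaluated subjects, as happens in
    rejection analysis once a whole class is rejected.
    """
    rows = cm.row_sums()
    if (rows == 0).any():
        return None
    return float(np.mean(list(sensitivities(cm).values())))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def kfold_cv(cohort: pd.DataFrame, config: StudyConfig, k: int = 10, seed: int = 0,
             modalities=None, normalize: bool = True,
             per_fold_normalization: bool = True) -> pd.DataFrame:
    """Out-of-fold predictions from stratified k-fold cross-validation.

    Folds are stratified by diagnosis with a fixed seed so every training
    split keeps all classes, which matters for the smallest class.  Nuisance
    regressions are, by default, refitted inside each training fold on that
    fold's controls only, so no information leaks from held-out subjects;
    ``per_fold_normalization=False`` reproduces the simpler recipe of fitting
    once on the full cohort before splitting.

    Returns one row per subject: true label, per-class total indices,
    predicted class, confidence, flag and fold number.
    """
    hierarchy = config.hierarchy
    if modalities is not None:
        hierarchy = hierarchy.restrict_to_modalities(modalities)
        if hierarchy is None:
            raise ValueError(f"no features in modalities {sorted(set(modalities))}")

    y = cohort[LABEL_COL].to_numpy()
    class_counts = pd.Series(y).value_counts()
    absent = [c for c in config.classes if c not in class_counts.index]
    if absent:
        raise ValueError(f"classes absent from cohort: {absent}")
    if int(class_counts.min()) < k:
        raise ValueError(
            f"smallest class has {int(class_counts.min())} subjects < k={k}; "
            f"use a smaller k"
        )

    normalizer_args = dict(
        modality_map=hierarchy.modality_of(),
        covariate_spec=config.covariate_spec,
        control_class=config.control_class,
        covariate_levels=config.covariate_levels,
    )
    working = cohort
    if normalize and not per_fold_normalization:
        working = NuisanceNormalizer(**normalizer_args).fit(cohort, y).transform(cohort)

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pieces = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        train, test = working.iloc[train_idx], working.iloc[test_idx]
        if normalize and per_fold_normalization:
            norm = NuisanceNormalizer(**normalizer_args).fit(train, train[LABEL_COL])
            train, test = norm.transform(train), norm.transform(test)
        clf = DSIClassifier(hierarchy=hierarchy, classes=config.classes,
                            normalization=config.normalization,
                            vascular_class=config.vascular_class)
        clf.fit(train, train[LABEL_COL])
        table = clf.predict_table(test, subject_ids=test[ID_COL].to_numpy())
        table.insert(1, "true", test[LABEL_COL].to_numpy())
        table["fold"] = fold
        pieces.append(table)
    out = pd.concat(pieces, ignore_index=True)
    assert len(out) == len(cohort) and out["subject_id"].is_unique
    return out


def confusion_from_table(predictions: pd.DataFrame, classes: list[str]) -> ConfusionMatrix:
    return ConfusionMatrix.from_predictions(predictions["true"], predictions["predicted"], classes)


def summarize(predictions: pd.DataFrame, classes: list[str]) -> dict:
    """Accuracy, balanced accuracy and per-class sensitivities (percent)."""
    cm = confusion_from_table(predictions, classes)
    return {
        "accuracy": accuracy(cm),
        "balanced_accuracy": balanced_accuracy(cm),
        "sensitivities": sensitivities(cm),
        "confusion": cm,
    }


# ---------------------------------------------------------------------------
# rejection analysis
# ---------------------------------------------------------------------------

@dataclass
class RejectionPoint:
    excluded_fraction: float
    cutoff: float
    n_retained: int
    accuracy: float
    balanced_accuracy: float | None
    retained_per_class: dict[str, int]
    left_out_percent: dict[str, float]
    sensitivities: dict[str, float]
    confusion: ConfusionMatrix


@dataclass
class RejectionCurve:
    classes: list[str]
    points: list[RejectionPoint] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        columns = ["excluded_fraction", "cutoff", "n_retained", "accuracy",
                   "balanced_accuracy"]
        for c in self.classes:
            columns.extend([f"retained_{c}", f"left_out_pct_{c}", f"sens_{c}"])
        rows = []
        for p in self.points:
            row = {
                "excluded_fraction": p.excluded_fraction,
                "cutoff": p.cutoff,
                "n_retained": p.n_retained,
                "accuracy": p.accuracy,
                "balanced_accuracy": p.balanced_accuracy,
            }
            for c in self.classes:
                row[f"retained_{c}"] = p.retained_per_class[c]
                row[f"left_out_pct_{c}"] = p.left_out_percent[c]
                row[f"sens_{c}"] = p.sensitivities[c]
            rows.append(row)
        return pd.DataFrame(rows, columns=columns)


def rejection_analysis(predictions: pd.DataFrame, excluded_fractions,
                       classes: list[str]) -> RejectionCurve:
    """Accuracy/coverage trade-off by rejecting the least confident subjects.

    For each fraction p the top ceil((1-p)*n) subjects by confidence are
    retained (ties broken by subject id for determinism), the cut-off is the
    minimum retained confidence, and the confusion-matrix metrics are
    recomputed on the retained subset.  Balanced accuracy becomes undefined
    once an entire class is rejected.
    """
    fracs = sorted(float(p) for p in excluded_fractions)
    if fracs and (fracs[0] < 0 or fracs[-1] >= 1):
        raise ValueError("excluded fractions must lie in [0, 1)")
    ordered = predictions.sort_values(
        ["confidence", "subject_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    n = len(ordered)
    totals = predictions["true"].value_counts()

    curve = RejectionCurve(classes=list(classes))
    for p in fracs:
        n_keep = math.ceil((1.0 - p) * n)
        kept = ordered.iloc[:n_keep]
        cm = confusion_from_table(kept, classes)
        retained = {c: int((kept["true"] == c).sum()) for c in classes}
        left_out = {
            c: 100.0 * (int(totals.get(c, 0)) - retained[c]) / int(totals.get(c, 1))
            if totals.get(c, 0) else float("nan")
            for c in classes
        }
        curve.points.append(RejectionPoint(
            excluded_fraction=p,
            cutoff=float(kept["confidence"].min()),
            n_retained=n_keep,
            accuracy=accuracy(cm),
            balanced_accuracy=balanced_accuracy(cm),
            retained_per_class=retained,
            left_out_percent=left_out,
            sensitivities=sensitivities(cm),
            confusion=cm,
        ))
    return curve


# ---------------------------------------------------------------------------
# ablations and complete-case analysis
# ---------------------------------------------------------------------------

def _all_subsets(modalities) -> list[tuple[str, ...]]:
    mods = list(modalities)
    out = []
    for r in range(1, len(mods) + 1):
        out.extend(combinations(mods, r))
    return out


def ablation(cohort: pd.DataFrame, config: StudyConfig, subsets=None, k: int = 10,
             seed: int = 0, normalize: bool = True) -> pd.DataFrame:
    """Cross-validated metrics per modality subset (feature-source ablation).

    ``subsets=None`` evaluates all 2^4 - 1 non-empty combinations of the four
    modalities present in the hierarchy.
    """
    present = sorted({leaf.modality for leaf in config.hierarchy.leaves()},
                     key=MODALITIES.index)
    if subsets is None:
        subsets = _all_subsets(present)
    rows = []
    for subset in subsets:
        subset = tuple(subset)
        if not subset:
            raise ValueError("empty modality subset")
        preds = kfold_cv(cohort, config, k=k, seed=seed, modalities=subset,
                         normalize=normalize)
        res = summarize(preds, config.classes)
        row = {"feature_set": "+".join(subset),
               "accuracy": res["accuracy"],
               "balanced_accuracy": res["balanced_accuracy"]}
        for c, s in res["sensitivities"].items():
            row[f"sens_{c}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_ablation(cohort: pd.DataFrame, config: StudyConfig, subsets=None,
                      k: int = 10, seed: int = 0, normalize: bool = True) -> pd.DataFrame:
    """Two-class balanced accuracies for every unordered class pair.

    Each pair is evaluated as its own cross-validated two-class problem on
    the subjects of those two classes, per modality subset.  Because most
    pairs contain no control subjects, nuisance regressions are fitted once
    on the full cohort's controls up front rather than per pair.
    """
    present = sorted({leaf.modality for leaf in config.hierarchy.leaves()},
                     key=MODALITIES.index)
    if subsets is None:
        subsets = _all_subsets(present)
    working = cohort
    if normalize:
        norm = NuisanceNormalizer(
            modality_map=config.hierarchy.modality_of(),
            covariate_spec=config.covariate_spec,
            control_class=config.control_class,
            covariate_levels=config.covariate_levels,
        ).fit(cohort, cohort[LABEL_COL])
        working = norm.transform(cohort)
    rows = []
    for subset in subsets:
        row: dict = {"feature_set": "+".join(subset)}
        for a, b in combinations(config.classes, 2):
            sub = working[working[LABEL_COL].isin([a, b])]
            pair_config = StudyConfig(
                classes=[a, b], hierarchy=config.hierarchy,
                control_class=(config.control_class
                               if config.control_class in (a, b) else a),
                vascular_class=(config.vascular_class
                                if config.vascular_class in (a, b) else None),
                normalization=config.normalization,
                covariate_spec=config.covariate_spec,
                covariate_levels=config.covariate_levels,
            )
            preds = kfold_cv(sub, pair_config, k=k, seed=seed, modalities=subset,
                             normalize=False)
            row[f"{a}_vs_{b}"] = summarize(preds, [a, b])["balanced_accuracy"]
        rows.append(row)
    return pd.DataFrame(rows)


def complete_case_filter(cohort: pd.DataFrame, features) -> pd.DataFrame:
    """Retain subjects with no missing values among the named features."""
    features = [f for f in features if f in cohort.columns]
    if not features:
        return cohort.copy()
    mask = cohort[features].notna().all(axis=1)
    return cohort.loc[mask].copy()
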