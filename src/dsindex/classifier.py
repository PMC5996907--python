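"""Multiclass Disease State Index classifier.

Combines one pairwise DSI model per ordered class pair (i, j), i != j, into a
K-class classifier.  For a subject, the total index of class i is the
(prior-weighted) mean of the K-1 pairwise indices DSI(i, j) against every
competing class; the subject is assigned to the class with the highest total
index, and that maximum is reported as the confidence of the decision.

Two normalization modes are supported.  The default, ``"pairs"``, divides the
sum of pairwise indices by K-1 (a true mean, so the total index spans [0, 1]);
``"classes"`` divides by K, which caps the total index at (K-1)/K.

The estimator follows scikit-learn conventions (``fit``/``predict``/
``decision_function``, ``get_params``, fitted attributes with a trailing
underscore) and accepts a pandas DataFrame whose columns include the features
named by the hierarchy; extra columns (identifiers, covariates) are ignored.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .hierarchy import FeatureHierarchy
from .pairwise import PairwiseDSIModel

logger = logging.getLogger(__name__)

_REVERSAL_TOL = 1e-9  # train-time self-check on DSI(j,i) = 1 - DSI(i,j)


def total_index(pairwise_scores: dict[tuple[str, str], float], class_name: str,
                n_classes: int, mode: str = "pairs",
                priors: dict[str, float] | None = None) -> float:
    """Total index of one class from its pairwise scores against all others.

    ``pairwise_scores`` maps ordered pairs to DSI(i, j); all pairs with
    ``i == class_name`` must be present.  With uniform priors, mode="pairs"
    returns the plain mean over the K-1 competitors and mode="classes" the sum
    divided by K.  Non-uniform priors weight each competitor j by its prior.
    """
    scores, weights = [], []
    for (i, j), s in pairwise_scores.items():
        if i == class_name:
            scores.append(s)
            weights.append(1.0 if priors is None else priors[j])
    if len(scores) != n_classes - 1:
        raise ValueError(
            f"class {class_name!r}: expected {n_classes - 1} pairwise scores, got {len(scores)}"
        )
    scores_arr = np.asarray(scores, float)
    weights_arr = np.asarray(weights, float)
    mean = float(scores_arr @ weights_arr / weights_arr.sum())
    if mode == "pairs":
        return mean
    if mode == "classes":
        return mean * (n_classes - 1) / n_classes
    raise ValueError(f"unknown normalization mode {mode!r}")


def classify(total_indices: dict[str, float], class_order: list[str] | None = None
             ) -> tuple[str, float]:
    """Argmax decision and confidence from per-class total indices.

    Ties are broken by the configured class order (first class wins) and
    logged; the confidence is the maximum total index itself.
    """
    if not total_indices:
        raise ValueError("no total indices supplied")
    order = class_order if class_order is not None else list(total_indices)
    best = max(total_indices.values())
    winners = [c for c in order if total_indices[c] == best]
    if len(winners) > 1:
        logger.warning("total-index tie between %s; first in class order wins", winners)
    return winners[0], float(best)


class DSIClassifier(ClassifierMixin, BaseEstimator):
    """Multiclass Disease State Index classifier.

    Parameters
    ----------
    hierarchy : FeatureHierarchy
        Feature tree with modality / structural / pair-restriction tags.
    classes : list of str, optional
        Class order; defaults to order of first appearance in ``y``.  The
        order fixes argmax tie-breaking and output column order.
    normalization : {"pairs", "classes"}
        Total-index divisor: K-1 (mean over competitors, default) or K.
    vascular_class : str, optional
        Class for which structural features are excluded from every pairwise
        model (no disease-specific structural signature), e.g. ``"VaD"``.
    priors : dict, optional
        Per-class prior weights used when averaging pairwise indices into
        total indices.  Default None = all diagnoses equally likely a priori.

    Attributes
    ----------
    classes_ : ndarray of class labels in configured order.
    pairwise_models_ : dict mapping ordered pair -> PairwiseDSIModel.
    """

    def __init__(self, hierarchy: FeatureHierarchy | None = None,
                 classes: list[str] | None = None,
                 normalization: str = "pairs",
                 vascular_class: str | None = None,
                 priors: dict[str, float] | None = None):
        self.hierarchy = hierarchy
        self.classes = classes
        self.normalization = normalization
        self.vascular_class = vascular_class
        self.priors = priors

    # ------------------------------------------------------------------ fit

    def fit(self, X: pd.DataFrame, y) -> "DSIClassifier":
        if self.hierarchy is None:
            raise ValueError("DSIClassifier requires a FeatureHierarchy")
        if self.normalization not in ("pairs", "classes"):
            raise ValueError(f"unknown normalization mode {self.normalization!r}")
        X = self._as_frame(X)
        y = np.asarray(y)
        if self.classes is not None:
            class_list = list(self.classes)
        else:
            class_list = list(pd.unique(pd.Series(y)))
        present = set(np.unique(y))
        missing = [c for c in class_list if c not in present]
        if missing:
            raise ValueError(f"classes absent from training data: {missing}")

        self.classes_ = np.asarray(class_list, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.pairwise_models_ = {}
        for i in class_list:
            for j in class_list:
                if i == j:
                    continue
                try:
                    self.pairwise_models_[(i, j)] = PairwiseDSIModel.fit(
                        X, y, self.hierarchy, (i, j), self.vascular_class
                    )
                except ValueError as exc:
                    raise ValueError(f"training pair ({i}, {j}) failed: {exc}") from exc
        self._check_reversal(X)
        return self

    def _check_reversal(self, X: pd.DataFrame, n_check: int = 25) -> None:
        """Self-check: DSI(j, i) must equal 1 - DSI(i, j) on training data."""
        sample = X.iloc[: min(n_check, len(X))]
        worst = 0.0
        for (i, j), model in self.pairwise_models_.items():
            if i >= j:
                continue
            s_ij = model.predict(sample)
            s_ji = self.pairwise_models_[(j, i)].predict(sample)
            worst = max(worst, float(np.max(np.abs(s_ij + s_ji - 1.0))))
        if worst > _REVERSAL_TOL:
            logger.warning("pair-reversal self-check deviation %.3g exceeds %.0e "
                           "(tied class means can break exact antisymmetry)",
                           worst, _REVERSAL_TOL)

    # -------------------------------------------------------------- predict

    def pairwise_scores(self, X: pd.DataFrame) -> tuple[dict[tuple[str, str], np.ndarray], np.ndarray]:
        """Pairwise DSI(i, j) arrays for each ordered pair, plus the
        all-features-missing flag per subject."""
        self._check_fitted()
        X = self._as_frame(X)
        scores: dict[tuple[str, str], np.ndarray] = {}
        all_missing = np.ones(len(X), dtype=bool)
        for pair, model in self.pairwise_models_.items():
            s, flag = model.decision_scores(X)
            scores[pair] = s
            all_missing &= flag
        return scores, all_missing

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Total index per class, shape (n_subjects, n_classes)."""
        scores, _ = self.pairwise_scores(X)
        return self._total_indices(scores)

    def _total_indices(self, scores: dict[tuple[str, str], np.ndarray]) -> np.ndarray:
        k = len(self.classes_)
        cols = []
        for i in self.classes_:
            weights = []
            vals = []
            for j in self.classes_:
                if j == i:
                    continue
                vals.append(scores[(i, j)])
                weights.append(1.0 if self.priors is None else self.priors[j])
            weights_arr = np.asarray(weights, float)
            col = np.stack(vals, axis=1) @ weights_arr / weights_arr.sum()
            if self.normalization == "classes":
                col *= (k - 1) / k
            cols.append(col)
        return np.stack(cols, axis=1)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        indices = self.decision_function(X)
        return self.classes_[np.argmax(indices, axis=1)]  # argmax picks first on ties

    def predict_table(self, X: pd.DataFrame, subject_ids=None) -> pd.DataFrame:
        """Full prediction record per subject.

        Columns: subject id, one total-index column per class (``dsi_<class>``),
        predicted class, confidence (max total index) and the
        no-usable-feature flag.
        """
        X = self._as_frame(X)
        scores, all_missing = self.pairwise_scores(X)
        indices = self._total_indices(scores)
        best = np.argmax(indices, axis=1)
        if subject_ids is None:
            subject_ids = np.asarray(X.index)
        out = pd.DataFrame({"subject_id": np.asarray(subject_ids)})
        for pos, c in enumerate(self.classes_):
            out[f"dsi_{c}"] = indices[:, pos]
        out["predicted"] = self.classes_[best]
        out["confidence"] = indices[np.arange(len(best)), best]
        out["flag_no_features"] = all_missing
        return out

    def branch_contributions(self, X: pd.DataFrame, predicted=None) -> pd.DataFrame:
        """Per-subject composite score of each modality branch.

        For each subject the branch composites of the pairwise models pitting
        the (given or predicted) class against every competitor are averaged,
        giving the text analogue of the per-subject fingerprint view: how
        strongly each measurement modality supports the predicted diagnosis.
        Branches with no usable feature stay missing.
        """
        X = self._as_frame(X)
        if predicted is None:
            predicted = self.predict(X)
        predicted = np.asarray(predicted)
        per_pair = {pair: model.branch_scores(X)
                    for pair, model in self.pairwise_models_.items()}
        branches = sorted({b for t in per_pair.values() for b in t.columns})
        out = pd.DataFrame(np.nan, index=X.index, columns=branches, dtype=float)
        for i in self.classes_:
            mask = predicted == i
            if not mask.any():
                continue
            frames = [per_pair[(i, j)].loc[mask] for j in self.classes_ if j != i]
            for b in branches:
                cols = np.stack([
                    f[b].to_numpy(float) if b in f.columns
                    else np.full(int(mask.sum()), np.nan)
                    for f in frames
                ], axis=1)
                seen = ~np.isnan(cols)
                n_seen = seen.sum(axis=1)
                total = np.where(seen, cols, 0.0).sum(axis=1)
                out.loc[mask, b] = np.where(n_seen > 0, total / np.maximum(n_seen, 1),
                                            np.nan)
        return out

    # ------------------------------------------------------------- helpers

    def _check_fitted(self) -> None:
        if not hasattr(self, "pairwise_models_"):
            raise ValueError("DSIClassifier is not fitted; call fit first")

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame with named feature columns")
        return X

    # ---------------------------------------------------------- persistence

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "classes": list(self.classes_),
            "normalization": self.normalization,
            "vascular_class": self.vascular_class,
            "priors": self.priors,
            "pairwise_models": {f"{i}|{j}": m.to_dict() for (i, j), m in self.pairwise_models_.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DSIClassifier":
        est = cls(classes=d["classes"], normalization=d["normalization"],
                  vascular_class=d.get("vascular_class"), priors=d.get("priors"))
        est.classes_ = np.asarray(d["classes"], dtype=object)
        est.pairwise_models_ = {}
        for key, md in d["pairwise_models"].items():
            i, j = key.split("|")
            est.pairwise_models_[(i, j)] = PairwiseDSIModel.from_dict(md)
        return est
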