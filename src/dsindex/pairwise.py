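"""Pairwise DSI model: hierarchical, missing-data-tolerant two-class index.

For an ordered class pair (i, j), a fitness model is fitted per retained
feature leaf, leaf scores are combined bottom-up through the feature
hierarchy by relevance-weighted means, and the root composite is the index
DSI(i, j) in [0, 1] — the degree to which a subject's measurements resemble
class i when class j is the alternative.

Pair-specific feature filtering happens before fitting: leaves restricted to
other class pairs are dropped, and structural features are dropped whenever
the vascular-dementia class is one of the two classes.  Missing values never
block a prediction: a missing leaf simply drops out of every weighted mean on
its path to the root, and a subject with no usable feature at all scores the
uninformative 0.5 and is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitness import FitnessModel, composite_scores, relevance_from_scores
from .hierarchy import FeatureGroup, FeatureHierarchy, FeatureLeaf

logger = logging.getLogger(__name__)


@dataclass
class NodeRelevance:
    """Relevance weight and training operating point of one tree node."""

    node: str
    pair: tuple[str, str]
    relevance: float
    sensitivity: float
    specificity: float


@dataclass
class PairwiseDSIModel:
    """Fitted two-class DSI for the ordered pair (positive, negative)."""

    pair: tuple[str, str]
    hierarchy: FeatureHierarchy
    fitness_models: dict[str, FitnessModel]
    relevances: dict[str, NodeRelevance] = field(default_factory=dict)

    # ------------------------------------------------------------------ fit

    @classmethod
    def fit(
        cls,
        X: pd.DataFrame,
        y: pd.Series | np.ndarray,
        hierarchy: FeatureHierarchy,
        pair: tuple[str, str],
        vascular_class: str | None = None,
    ) -> "PairwiseDSIModel":
        """Train on the subjects of the two classes of ``pair``.

        ``X`` holds feature columns (extra columns are ignored); ``y`` holds
        diagnosis labels aligned with ``X``.
        """
        i, j = pair
        y = np.asarray(y)
        for cls_name in pair:
            if np.count_nonzero(y == cls_name) < 2:
                raise ValueError(
                    f"pair ({i}, {j}): class {cls_name!r} has fewer than 2 training subjects"
                )
        pos = X.loc[y == i]
        neg = X.loc[y == j]

        pruned = hierarchy.prune(lambda leaf: leaf.allowed_for_pair(i, j, vascular_class))
        if pruned is None:
            raise ValueError(f"pair ({i}, {j}): no features remain after pair-specific filtering")

        # drop leaves fully missing in either class; fit fitness models
        fitness_models: dict[str, FitnessModel] = {}
        for leaf in pruned.leaves():
            vp = pos[leaf.name].dropna().to_numpy(float)
            vn = neg[leaf.name].dropna().to_numpy(float)
            if vp.size == 0 or vn.size == 0:
                logger.warning(
                    "pair (%s, %s): feature %r fully missing in one class; leaf dropped",
                    i, j, leaf.name,
                )
                continue
            fitness_models[leaf.name] = FitnessModel(leaf.name, (i, j), vp, vn)
        if not fitness_models:
            raise ValueError(f"pair ({i}, {j}): every feature is fully missing in one class")
        pruned = pruned.prune(lambda leaf: leaf.name in fitness_models)
        assert pruned is not None

        model = cls(pair=(i, j), hierarchy=pruned, fitness_models=fitness_models)
        model._fit_relevances(pos, neg)
        return model

    def _fit_relevances(self, pos: pd.DataFrame, neg: pd.DataFrame) -> None:
        """Bottom-up pass computing training scores and node relevances.

        Leaf relevance comes from leaf fitness scores of the training
        subjects; each internal node's relevance is recomputed from that
        node's own composite training scores, so deep and shallow branches
        are weighted on the same footing.
        """
        n_pos = len(pos)

        def _scores(node: FeatureGroup | FeatureLeaf, frame_pos: pd.DataFrame,
                    frame_neg: pd.DataFrame) -> np.ndarray:
            if isinstance(node, FeatureLeaf):
                fm = self.fitness_models[node.name]
                x = np.concatenate([frame_pos[node.name].to_numpy(float),
                                    frame_neg[node.name].to_numpy(float)])
                out = np.full(x.shape, np.nan)
                seen = ~np.isnan(x)
                out[seen] = fm(x[seen])
                key = node.name
            else:
                child_scores = np.column_stack(
                    [_scores(c, frame_pos, frame_neg) for c in node.children]
                )
                rel = np.array([self._node_relevance_value(c) for c in node.children])
                out = composite_scores(child_scores, rel)
                key = node.name
            sp = out[:n_pos]
            sn = out[n_pos:]
            sp = sp[~np.isnan(sp)]
            sn = sn[~np.isnan(sn)]
            if sp.size and sn.size:
                sens, spec, rel_w = relevance_from_scores(sp, sn)
            else:  # node unobserved in one class: carries no weight
                sens, spec, rel_w = 0.0, 0.0, 0.0
            self.relevances[key] = NodeRelevance(key, self.pair, rel_w, sens, spec)
            return out

        _scores(self.hierarchy.root, pos, neg)

    def _node_relevance_value(self, node: FeatureGroup | FeatureLeaf) -> float:
        return self.relevances[node.name].relevance

    # -------------------------------------------------------------- predict

    def _node_scores(self, node: FeatureGroup | FeatureLeaf, X: pd.DataFrame) -> np.ndarray:
        if isinstance(node, FeatureLeaf):
            x = X[node.name].to_numpy(float)
            out = np.full(x.shape, np.nan)
            seen = ~np.isnan(x)
            out[seen] = self.fitness_models[node.name](x[seen])
            return out
        child_scores = np.column_stack([self._node_scores(c, X) for c in node.children])
        rel = np.array([self._node_relevance_value(c) for c in node.children])
        return composite_scores(child_scores, rel)

    def decision_scores(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Root composite per subject plus a no-usable-feature flag.

        Subjects whose every usable feature is missing get the uninformative
        score 0.5 and ``flag=True``.
        """
        raw = self._node_scores(self.hierarchy.root, X)
        flags = np.isnan(raw)
        return np.where(flags, 0.5, raw), flags

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.decision_scores(X)[0]

    def branch_scores(self, X: pd.DataFrame) -> pd.DataFrame:
        """Composite score of each top-level branch (modality), for reports."""
        cols = {}
        for child in self.hierarchy.root.children:
            cols[child.name] = self._node_scores(child, X)
        return pd.DataFrame(cols, index=X.index)

    # ---------------------------------------------------------- persistence

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "hierarchy": self.hierarchy.to_dict(),
            "fitness_models": {k: m.to_dict() for k, m in self.fitness_models.items()},
            "relevances": {
                k: {"relevance": r.relevance, "sensitivity": r.sensitivity,
                    "specificity": r.specificity}
                for k, r in self.relevances.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PairwiseDSIModel":
        pair = tuple(d["pair"])
        model = cls(
            pair=pair,
            hierarchy=FeatureHierarchy.from_dict(d["hierarchy"]),
            fitness_models={k: FitnessModel.from_dict(m) for k, m in d["fitness_models"].items()},
            relevances={
                k: NodeRelevance(k, pair, r["relevance"], r["sensitivity"], r["specificity"])
                for k, r in d["relevances"].items()
            },
        )
        return model
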