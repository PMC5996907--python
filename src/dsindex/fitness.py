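"""Per-feature fitness functions and relevance weights of the two-class DSI.

A fitness function maps a measurement value ``x`` to [0, 1] via the error
rates that value would incur if used as a classification threshold between
the two training populations.  With polarity +1 (positive class tends to have
higher values)::

    FN(x) = (#{pos < x} + 0.5 * #{pos == x}) / n_pos
    FP(x) = (#{neg > x} + 0.5 * #{neg == x}) / n_neg
    fitness(x) = FN(x) / (FN(x) + FP(x))

and polarity -1 mirrors all inequalities.  Midpoint weights on ties make the
construction exactly antisymmetric under swapping the two classes, so the
two-class index satisfies DSI(j, i) = 1 - DSI(i, j).  When FN + FP = 0 (a
value in the gap between two perfectly separated samples) the fitness is 0.5,
the maximally uncertain score.

Relevance is the Youden index of a score variable thresholded at 0.5,
clamped at zero so composite weights stay non-negative::

    sensitivity = (#{pos score > 0.5} + 0.5 * #{== 0.5}) / n_pos
    specificity = (#{neg score < 0.5} + 0.5 * #{== 0.5}) / n_neg
    relevance   = max(0, sensitivity + specificity - 1)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FitnessModel:
    """Empirical fitness function for one feature and one ordered class pair.

    Stores the sorted non-missing training values of the positive class
    (class ``i`` of the ordered pair) and the negative class (class ``j``).
    """

    feature: str
    pair: tuple[str, str]
    values_pos: np.ndarray
    values_neg: np.ndarray
    polarity: int = field(init=False)

    def __post_init__(self) -> None:
        self.values_pos = np.sort(np.asarray(self.values_pos, dtype=float))
        self.values_neg = np.sort(np.asarray(self.values_neg, dtype=float))
        for side, vals in (("positive", self.values_pos), ("negative", self.values_neg)):
            if vals.size == 0:
                raise ValueError(
                    f"feature {self.feature!r}, pair {self.pair}: "
                    f"empty {side}-class training sample"
                )
            if not np.all(np.isfinite(vals)):
                raise ValueError(
                    f"feature {self.feature!r}, pair {self.pair}: "
                    f"non-finite {side}-class training values"
                )
        # tie in class means defaults to +1
        self.polarity = 1 if self.values_pos.mean() >= self.values_neg.mean() else -1

    @property
    def n_pos(self) -> int:
        return int(self.values_pos.size)

    @property
    def n_neg(self) -> int:
        return int(self.values_neg.size)

    def error_rates(self, x) -> tuple[np.ndarray, np.ndarray]:
        """False-negative and false-positive rates of threshold ``x`` (vectorised)."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"feature {self.feature!r}: non-finite evaluation value")
        lo_p = np.searchsorted(self.values_pos, x, side="left")
        hi_p = np.searchsorted(self.values_pos, x, side="right")
        lo_n = np.searchsorted(self.values_neg, x, side="left")
        hi_n = np.searchsorted(self.values_neg, x, side="right")
        eq_p, eq_n = hi_p - lo_p, hi_n - lo_n
        if self.polarity == 1:
            fn = (lo_p + 0.5 * eq_p) / self.n_pos            # pos below x
            fp = ((self.n_neg - hi_n) + 0.5 * eq_n) / self.n_neg  # neg above x
        else:
            fn = ((self.n_pos - hi_p) + 0.5 * eq_p) / self.n_pos  # pos above x
            fp = (lo_n + 0.5 * eq_n) / self.n_neg            # neg below x
        return fn, fp

    def __call__(self, x) -> np.ndarray:
        """Evaluate fitness(x) in [0, 1]; 0/0 (separated-classes gap) -> 0.5."""
        fn, fp = self.error_rates(x)
        total = fn + fp
        with np.errstate(invalid="ignore"):
            out = np.where(total > 0, fn / np.where(total > 0, total, 1.0), 0.5)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "pair": list(self.pair),
            "values_pos": self.values_pos.tolist(),
            "values_neg": self.values_neg.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitnessModel":
        return cls(d["feature"], tuple(d["pair"]), np.array(d["values_pos"]), np.array(d["values_neg"]))


def fit_fitness(values_pos, values_neg, feature: str = "", pair: tuple[str, str] = ("i", "j")) -> FitnessModel:
    """Fit an empirical fitness model from the two class samples."""
    return FitnessModel(feature, pair, np.asarray(values_pos, float), np.asarray(values_neg, float))


#: scores within this distance of the 0.5 cutoff count as ties.  Composite
#: scores that are exactly 0.5 analytically (e.g. built from gap-valued leaf
#: fitnesses) land on either side of the cutoff after rounding, and the
#: rounding differs between the (i, j) and (j, i) orderings; a small tie band
#: keeps relevance — and hence the pair-reversal identity — exact.
CUTOFF_TIE_TOL = 1e-9


def relevance_from_scores(scores_pos, scores_neg) -> tuple[float, float, float]:
    """(sensitivity, specificity, relevance) of scores at the 0.5 cutoff.

    Relevance is the clamped Youden index max(0, sens + spec - 1); it is zero
    whenever the two score samples are identically distributed around 0.5 and
    reaches 1 only for perfect separation.  Scores within ``CUTOFF_TIE_TOL``
    of the cutoff take midpoint weight 0.5.
    """
    sp = np.asarray(scores_pos, dtype=float)
    sn = np.asarray(scores_neg, dtype=float)
    if sp.size == 0 or sn.size == 0:
        raise ValueError("relevance requires non-empty score samples for both classes")
    if sp.min() < 0 or sp.max() > 1 or sn.min() < 0 or sn.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    tol = CUTOFF_TIE_TOL
    sens = (np.count_nonzero(sp > 0.5 + tol)
            + 0.5 * np.count_nonzero(np.abs(sp - 0.5) <= tol)) / sp.size
    spec = (np.count_nonzero(sn < 0.5 - tol)
            + 0.5 * np.count_nonzero(np.abs(sn - 0.5) <= tol)) / sn.size
    return float(sens), float(spec), float(max(0.0, sens + spec - 1.0))


def composite_scores(child_scores: np.ndarray, relevances: np.ndarray) -> np.ndarray:
    """Relevance-weighted mean over children, tolerant of missing values.

    Parameters
    ----------
    child_scores : (n_subjects, n_children) array with NaN for missing.
    relevances : (n_children,) non-negative weights.

    Returns (n_subjects,) scores; NaN where no child with positive relevance
    has a score.  Invariant to rescaling all relevances by a positive factor.
    """
    scores = np.atleast_2d(np.asarray(child_scores, dtype=float))
    rel = np.asarray(relevances, dtype=float)
    usable = ~np.isnan(scores) & (rel > 0)
    weights = np.where(usable, rel, 0.0)
    denom = weights.sum(axis=1)
    num = np.where(usable, scores, 0.0)
    num = (num * weights).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return out
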