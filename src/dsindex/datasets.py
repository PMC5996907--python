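"""Packaged reference results of the published PredictND evaluation.

The clinical cohort the multiclass DSI classifier was originally evaluated on
(a tertiary memory-clinic population of 504 subjects) is not public, but the
published confusion matrices are, and they anchor the metric computations:

``load_reference_confusion("all_features")``
    5x5 confusion matrix of the 10-fold cross-validated classifier using all
    four measurement modalities (504 subjects).
``load_reference_confusion("top50_confidence")``
    Confusion matrix restricted to the 50% of subjects the classifier was
    most confident about (251 subjects retained).

Rows are the true class, columns the predicted class, in the order
CN, AD, FTLD, DLB, VaD.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import ConfusionMatrix

#: diagnostic-group sizes of the reference cohort
REFERENCE_CLASS_SIZES = {"CN": 118, "AD": 223, "FTLD": 92, "DLB": 47, "VaD": 24}

_FILES = {
    "all_features": "confusion_all_features.csv",
    "top50_confidence": "confusion_top50_confidence.csv",
}


def load_reference_confusion(which: str = "all_features") -> ConfusionMatrix:
    """Load one of the packaged reference confusion matrices."""
    if which not in _FILES:
        raise ValueError(f"unknown reference matrix {which!r}; choose from {sorted(_FILES)}")
    with resources.files("dsindex.data").joinpath(_FILES[which]).open() as fh:
        frame = pd.read_csv(fh, index_col=0)
    return ConfusionMatrix(list(frame.index), frame.to_numpy())
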