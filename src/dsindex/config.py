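"""Study configuration: class set, feature hierarchy, nuisance covariates.

A :class:`StudyConfig` bundles everything the classifier and evaluation
harness need to know about a cohort besides the data itself.  It can be read
from / written to a YAML file with keys ``classes``, ``control_class``,
``vascular_class``, ``normalization``, ``nuisance`` (modality -> covariate
list), ``covariate_levels`` and ``hierarchy``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hierarchy import FeatureHierarchy
from .preprocessing import DEFAULT_COVARIATE_LEVELS, DEFAULT_COVARIATE_SPEC

#: canonical cohort-table column names
ID_COL = "subject_id"
LABEL_COL = "diagnosis"
COVARIATE_COLS = ("age", "sex", "education", "scanner")

DEFAULT_CLASSES = ["CN", "AD", "FTLD", "DLB", "VaD"]


@dataclass
class StudyConfig:
    """Everything needed to train and evaluate the DSI on one cohort layout."""

    classes: list[str]
    hierarchy: FeatureHierarchy
    control_class: str = "CN"
    vascular_class: str | None = "VaD"
    normalization: str = "pairs"
    covariate_spec: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_COVARIATE_SPEC.items()})
    covariate_levels: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_COVARIATE_LEVELS.items()})

    def __post_init__(self) -> None:
        if self.control_class not in self.classes:
            raise ValueError(
                f"control class {self.control_class!r} not in class set {self.classes}")
        if self.vascular_class is not None and self.vascular_class not in self.classes:
            raise ValueError(
                f"vascular class {self.vascular_class!r} not in class set {self.classes}")

    @property
    def feature_names(self) -> list[str]:
        return self.hierarchy.feature_names

    def modality_map(self) -> dict[str, str]:
        return self.hierarchy.modality_of()

    # ------------------------------------------------------------- file I/O

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {"classes", "control_class", "vascular_class", "normalization",
                 "nuisance", "covariate_levels", "hierarchy"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hierarchy" not in d or "classes" not in d:
            raise ValueError("config requires 'classes' and 'hierarchy' sections")
        kwargs = dict(
            classes=list(d["classes"]),
            hierarchy=FeatureHierarchy.from_dict(d["hierarchy"]),
        )
        if "control_class" in d:
            kwargs["control_class"] = d["control_class"]
        if "vascular_class" in d:
            kwargs["vascular_class"] = d["vascular_class"]
        if "normalization" in d:
            kwargs["normalization"] = d["normalization"]
        if "nuisance" in d:
            kwargs["covariate_spec"] = {k: list(v or []) for k, v in d["nuisance"].items()}
        if "covariate_levels" in d:
            kwargs["covariate_levels"] = {k: list(v) for k, v in d["covariate_levels"].items()}
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "control_class": self.control_class,
            "vascular_class": self.vascular_class,
            "normalization": self.normalization,
            "nuisance": {k: list(v) for k, v in self.covariate_spec.items()},
            "covariate_levels": {k: list(v) for k, v in self.covariate_levels.items()},
            "hierarchy": self.hierarchy.to_dict(),
        }

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
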