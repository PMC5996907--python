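"""Synthetic multimodal memory-clinic cohorts.

No public dataset carries the structure the classifier needs (five diagnostic
groups, four feature modalities, nuisance covariates and class-dependent
missingness), so this module generates one.  The default configuration
emulates a tertiary memory-clinic case mix: 504 subjects split 118/223/92/47/24
across controls with subjective cognitive decline (CN), Alzheimer's disease
(AD), frontotemporal lobar degeneration (FTLD), dementia with Lewy bodies
(DLB) and vascular dementia (VaD); per-class age, sex and scanner
distributions matching that case mix; a 29-feature panel (12 neuropsychological
tests, 3 CSF biomarkers, 4 visual MRI ratings, 10 automatic MRI
quantifications); and class-conditional missingness of the neuropsychological
tests at the observed per-test rates (tests are skipped more often in some
diagnostic groups than others, so missingness is informative about class).

Features are Gaussian within class: value = class mean + linear covariate
effects (age, sex, education, scanner) + noise.  Two presets control class
separation: ``preset_null`` gives every class the same means (a cohort where
nothing but guessing is possible), and ``preset_separable(delta)`` spreads
class means so that every class pair differs by ``delta`` standard deviations
on several features in every modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import DEFAULT_CLASSES, ID_COL, LABEL_COL, StudyConfig
from .hierarchy import MODALITIES, FeatureGroup, FeatureHierarchy, FeatureLeaf

AGE_CENTER = 65.0  # years; covariate effects are relative to this age
EDU_CENTER = 5.0   # Verhage level around which education effects are centred

#: memory-clinic case mix the defaults emulate
DEFAULT_CLASS_SIZES = {"CN": 118, "AD": 223, "FTLD": 92, "DLB": 47, "VaD": 24}
DEFAULT_AGE = {"CN": (61, 9), "AD": (66, 7), "FTLD": (63, 7), "DLB": (68, 9), "VaD": (69, 6)}
DEFAULT_FEMALE_PROP = {"CN": 0.38, "AD": 0.54, "FTLD": 0.45, "DLB": 0.13, "VaD": 0.38}
DEFAULT_EDUCATION_PROBS = (0.02, 0.05, 0.13, 0.20, 0.30, 0.20, 0.10)  # Verhage 1..7
DEFAULT_SCANNER_PROBS = {"1.0T": 85 / 504, "1.5T": 98 / 504, "3.0T": 321 / 504}

#: per-class probability that each neuropsychological test was NOT performed
DEFAULT_NP_MISSINGNESS = {
    "mmse":       {"CN": 0.00, "AD": 0.00, "FTLD": 0.00, "DLB": 0.00, "VaD": 0.00},
    "camcog":     {"CN": 0.47, "AD": 0.00, "FTLD": 0.43, "DLB": 0.26, "VaD": 0.25},
    "vat":        {"CN": 0.00, "AD": 0.01, "FTLD": 0.07, "DLB": 0.00, "VaD": 0.00},
    "ravlt":      {"CN": 0.00, "AD": 0.05, "FTLD": 0.26, "DLB": 0.04, "VaD": 0.00},
    "cft":        {"CN": 0.00, "AD": 0.00, "FTLD": 0.12, "DLB": 0.00, "VaD": 0.08},
    "tmt":        {"CN": 0.00, "AD": 0.05, "FTLD": 0.05, "DLB": 0.06, "VaD": 0.00},
    "fab":        {"CN": 0.24, "AD": 0.13, "FTLD": 0.30, "DLB": 0.21, "VaD": 0.17},
    "stroop":     {"CN": 0.02, "AD": 0.08, "FTLD": 0.30, "DLB": 0.09, "VaD": 0.08},
    "rey_figure": {"CN": 0.34, "AD": 0.74, "FTLD": 0.59, "DLB": 0.51, "VaD": 0.54},
    "gds":        {"CN": 0.07, "AD": 0.05, "FTLD": 0.23, "DLB": 0.13, "VaD": 0.21},
    "dad":        {"CN": 0.60, "AD": 0.07, "FTLD": 0.51, "DLB": 0.34, "VaD": 0.54},
    "npi":        {"CN": 0.31, "AD": 0.00, "FTLD": 0.26, "DLB": 0.00, "VaD": 0.33},
}


@dataclass
class FeatureSim:
    """Generative description of one feature."""

    name: str
    modality: str
    class_means: dict[str, float]
    sd: float = 1.0
    structural: bool = False
    pair_restriction: list[list[str]] | None = None
    age_beta: float = 0.0          # per year of age relative to AGE_CENTER
    sex_beta: float = 0.0          # additive effect of female sex
    edu_beta: float = 0.0          # per Verhage level relative to EDU_CENTER
    scanner_offsets: dict[str, float] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=dict)  # class -> prob

    def leaf(self) -> FeatureLeaf:
        restriction = None
        if self.pair_restriction is not None:
            restriction = frozenset(frozenset(p) for p in self.pair_restriction)
        return FeatureLeaf(self.name, self.modality, self.structural, restriction)


@dataclass
class SimulationConfig:
    """Full generative recipe for one synthetic cohort."""

    classes: list[str] = field(default_factory=lambda: list(DEFAULT_CLASSES))
    class_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    age: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_AGE))
    female_prop: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FEMALE_PROP))
    education_probs: tuple[float, ...] = DEFAULT_EDUCATION_PROBS
    scanner_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCANNER_PROBS))
    features: list[FeatureSim] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for c, n in self.class_sizes.items():
            if n < 1:
                raise ValueError(f"class_sizes[{c!r}] must be >= 1, got {n}")
        for f in self.features:
            if f.sd <= 0:
                raise ValueError(f"features[{f.name!r}].sd must be > 0")
            for c, p in f.missingness.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"features[{f.name!r}].missingness[{c!r}] must be in [0, 1]")

    def hierarchy(self) -> FeatureHierarchy:
        groups = []
        for modality in MODALITIES:
            leaves = [f.leaf() for f in self.features if f.modality == modality]
            if leaves:
                groups.append(FeatureGroup(modality, leaves))
        return FeatureHierarchy(FeatureGroup("all", groups))

    def study_config(self, **overrides) -> StudyConfig:
        kwargs = dict(classes=list(self.classes), hierarchy=self.hierarchy(),
                      control_class="CN", vascular_class="VaD")
        kwargs.update(overrides)
        return StudyConfig(**kwargs)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "class_sizes": dict(self.class_sizes),
            "age": {c: list(v) for c, v in self.age.items()},
            "female_prop": dict(self.female_prop),
            "education_probs": list(self.education_probs),
            "scanner_probs": dict(self.scanner_probs),
            "seed": self.seed,
            "features": [
                {
                    "name": f.name, "modality": f.modality,
                    "class_means": dict(f.class_means), "sd": f.sd,
                    "structural": f.structural,
                    "pair_restriction": f.pair_restriction,
                    "age_beta": f.age_beta, "sex_beta": f.sex_beta,
                    "edu_beta": f.edu_beta,
                    "scanner_offsets": dict(f.scanner_offsets),
                    "missingness": dict(f.missingness),
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        feats = [FeatureSim(**{**f, "pair_restriction": f.get("pair_restriction")})
                 for f in d.pop("features", [])]
        if "age" in d:
            d["age"] = {c: tuple(v) for c, v in d["age"].items()}
        if "education_probs" in d:
            d["education_probs"] = tuple(d["education_probs"])
        return cls(features=feats, **d)


# ---------------------------------------------------------------------------
# default feature panel and presets
# ---------------------------------------------------------------------------

_PANEL = [
    # name, modality, structural, pair_restriction
    *[(name, "NP", False, None) for name in DEFAULT_NP_MISSINGNESS],
    ("abeta_42", "CSF", False, None),
    ("t_tau", "CSF", False, None),
    ("p_tau", "CSF", False, None),
    ("mta", "VMRI", True, None),
    ("gca", "VMRI", True, None),
    ("fazekas", "VMRI", False, None),
    ("lacunes", "VMRI", False, None),
    ("vol_hippocampus", "AMRI", True, None),
    ("vol_medial_temporal", "AMRI", True, None),
    ("vol_frontal", "AMRI", True, None),
    ("vol_ventricles", "AMRI", True, None),
    ("gm_concentration", "AMRI", True, None),
    ("roi_grading", "AMRI", True, None),
    ("manifold_coord", "AMRI", True, None),
    ("tbm_cn_ad", "AMRI", True, [["CN", "AD"]]),
    ("vbm_ad_ftld", "AMRI", True, [["AD", "FTLD"]]),
    ("vascular_burden", "AMRI", False, None),
]

_COVARIATE_EFFECTS = {
    # modality -> (age_beta, sex_beta, edu_beta, scanner_offsets)
    "NP": (-0.02, 0.0, 0.12, {}),
    "CSF": (0.015, 0.10, 0.0, {}),
    "VMRI": (0.015, 0.0, 0.0, {}),
    "AMRI": (-0.02, 0.0, 0.0, {"1.0T": -0.4}),
}


def _default_features(mean_table: dict[str, dict[str, float]]) -> list[FeatureSim]:
    feats = []
    for name, modality, structural, restriction in _PANEL:
        age_b, sex_b, edu_b, scan = _COVARIATE_EFFECTS[modality]
        feats.append(FeatureSim(
            name=name, modality=modality,
            class_means=mean_table[name], sd=1.0,
            structural=structural, pair_restriction=restriction,
            age_beta=age_b, sex_beta=sex_b, edu_beta=edu_b,
            scanner_offsets=dict(scan),
            missingness=dict(DEFAULT_NP_MISSINGNESS.get(name, {})),
        ))
    return feats


def preset_null(**overrides) -> SimulationConfig:
    """Zero class separation: identical feature distributions in every class."""
    return preset_separable(0.0, **overrides)


def preset_separable(delta: float, **overrides) -> SimulationConfig:
    """Cohort where every class pair differs by ``delta`` sd on many features.

    Features are assigned round-robin to the five classes; an assigned feature
    has mean ``delta`` (in sd units) in its class and 0 elsewhere, so every
    class pair differs by ``delta`` sd on all features assigned to either
    class — at least 10 of the 29 panel features, spread over modalities.
    ``delta=0`` reduces to the null preset.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    classes = list(overrides.pop("classes", DEFAULT_CLASSES))
    mean_table = {}
    for idx, (name, _, _, _) in enumerate(_PANEL):
        owner = classes[idx % len(classes)]
        mean_table[name] = {c: (float(delta) if c == owner else 0.0) for c in classes}
    config = SimulationConfig(classes=classes,
                              features=_default_features(mean_table))
    return replace(config, **overrides) if overrides else config


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig, seed: int | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Sample a cohort table and return it with its ground-truth record.

    Fully reproducible: the same config and seed give an identical table.
    Covariates are drawn per class, feature values follow the linear Gaussian
    model, and missingness is applied as independent class-conditional
    Bernoulli draws per feature.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    edu_levels = np.arange(1, len(config.education_probs) + 1)
    edu_p = np.asarray(config.education_probs, float)
    edu_p = edu_p / edu_p.sum()
    scanner_levels = list(config.scanner_probs)
    scan_p = np.asarray([config.scanner_probs[s] for s in scanner_levels], float)
    scan_p = scan_p / scan_p.sum()

    frames = []
    offset = 0
    for cls in config.classes:
        n = config.class_sizes[cls]
        mu, sd = config.age[cls]
        age = rng.normal(mu, sd, size=n)
        sex = np.where(rng.random(n) < config.female_prop[cls], "F", "M")
        education = rng.choice(edu_levels, size=n, p=edu_p)
        scanner = rng.choice(scanner_levels, size=n, p=scan_p)
        row = {
            ID_COL: [f"S{offset + i + 1:04d}" for i in range(n)],
            LABEL_COL: cls,
            "age": age,
            "sex": sex,
            "education": education,
            "scanner": scanner,
        }
        female = (sex == "F").astype(float)
        for f in config.features:
            scan_off = np.array([f.scanner_offsets.get(s, 0.0) for s in scanner])
            values = (
                f.class_means[cls]
                + f.age_beta * (age - AGE_CENTER)
                + f.sex_beta * female
                + f.edu_beta * (education - EDU_CENTER)
                + scan_off
                + rng.normal(0.0, f.sd, size=n)
            )
            p_miss = f.missingness.get(cls, 0.0)
            if p_miss > 0:
                values = np.where(rng.random(n) < p_miss, np.nan, values)
            row[f.name] = values
        frames.append(pd.DataFrame(row))
        offset += n
    cohort = pd.concat(frames, ignore_index=True)
    truth = {"config": config.to_dict(), "seed": int(config.seed if seed is None else seed),
             "n_subjects": int(len(cohort))}
    return cohort, truth
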