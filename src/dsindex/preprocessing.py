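"""Removal of nuisance variability by control-group linear regression.

Biomarkers vary with age, sex, education and MRI scanner field strength for
reasons unrelated to disease.  Following the standard residualization recipe,
an ordinary-least-squares model is fitted per feature on the *control group
only*, with the feature's nuisance covariates as explanatory variables; the
model's prediction is then subtracted from every subject's observed value, so
the corrected feature expresses deviation from the covariate-expected norm.

Which covariates apply is modality-specific: neuropsychological tests are
corrected for age, sex and education; CSF biomarkers for age and sex;
automatic MRI quantifications for age, sex and scanner type; visual MRI
ratings are not corrected at all (empty covariate set = identity).

The transformer is scikit-learn style: ``fit(X, y)`` learns the control-group
regressions (``y`` supplies diagnosis labels to locate controls), and
``transform(X)`` residualizes feature columns in place, leaving covariate and
identifier columns untouched, so it composes with ``DSIClassifier`` in a
``sklearn.pipeline.Pipeline``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: covariates used per modality when none are configured explicitly
DEFAULT_COVARIATE_SPEC: dict[str, list[str]] = {
    "NP": ["age", "sex", "education"],
    "CSF": ["age", "sex"],
    "VMRI": [],
    "AMRI": ["age", "sex", "scanner"],
}

#: categorical covariates and their level order (first level = reference)
DEFAULT_COVARIATE_LEVELS: dict[str, list[str]] = {
    "sex": ["F", "M"],
    "scanner": ["1.0T", "1.5T", "3.0T"],
}


@dataclass
class DesignSpec:
    """Design-matrix layout for one covariate set (intercept always first)."""

    covariates: list[str]
    levels: dict[str, list[str]]
    columns: list[str]

    @classmethod
    def build(cls, covariates: list[str], levels: dict[str, list[str]]) -> "DesignSpec":
        cols = ["intercept"]
        for cov in covariates:
            if cov in levels:
                cols.extend(f"{cov}[{lv}]" for lv in levels[cov][1:])  # drop reference
            else:
                cols.append(cov)
        return cls(list(covariates), levels, cols)

    def matrix(self, table: pd.DataFrame) -> np.ndarray:
        """Design rows for ``table``; NaN marks a missing covariate's terms."""
        unknown = [c for c in self.covariates if c not in table.columns]
        if unknown:
            raise ValueError(f"covariates not present in the table: {unknown}")
        n = len(table)
        out = [np.ones(n)]
        for cov in self.covariates:
            col = table[cov]
            if cov in self.levels:
                lvls = self.levels[cov]
                vals = col.astype(object)
                known = vals.isin(lvls) | vals.isna()
                if not known.all():
                    bad = sorted(set(vals[~known]))
                    raise ValueError(f"covariate {cov!r}: unknown levels {bad}")
                for lv in lvls[1:]:
                    ind = np.where(vals.isna(), np.nan, (vals == lv).astype(float))
                    out.append(ind.astype(float))
            else:
                out.append(pd.to_numeric(col, errors="raise").to_numpy(float))
        return np.column_stack(out)


def build_design(covariates: pd.DataFrame, spec: list[str],
                 levels: dict[str, list[str]] | None = None) -> np.ndarray:
    """Numeric design rows (with intercept) for the named covariates.

    Numeric covariates pass through; categoricals are one-hot encoded with the
    first configured level as the reference; education is treated as a numeric
    ordinal on the 1-7 Verhage scale.
    """
    return DesignSpec.build(spec, levels or DEFAULT_COVARIATE_LEVELS).matrix(covariates)


class NuisanceNormalizer(TransformerMixin, BaseEstimator):
    """Residualize features against nuisance covariates fitted on controls.

    Parameters
    ----------
    modality_map : dict
        Feature name -> modality tag; features absent from the map (or whose
        modality has an empty covariate list) pass through unchanged.
    covariate_spec : dict
        Modality -> list of covariate column names (default: the standard
        per-modality sets above).
    control_class : str
        Diagnosis label of the control group (default ``"CN"``).
    covariate_levels : dict
        Categorical covariate -> ordered levels, first level as reference.

    Attributes
    ----------
    coef_ : dict feature -> ndarray of regression coefficients (aligned with
        the feature's design columns), for corrected features only.
    design_means_ : dict feature -> control-group mean of each design column,
        used to fill missing covariates at transform time.
    """

    def __init__(self, modality_map: dict[str, str] | None = None,
                 covariate_spec: dict[str, list[str]] | None = None,
                 control_class: str = "CN",
                 covariate_levels: dict[str, list[str]] | None = None):
        self.modality_map = modality_map
        self.covariate_spec = covariate_spec
        self.control_class = control_class
        self.covariate_levels = covariate_levels

    def _resolved_specs(self) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
        spec = self.covariate_spec if self.covariate_spec is not None else DEFAULT_COVARIATE_SPEC
        levels = self.covariate_levels if self.covariate_levels is not None else DEFAULT_COVARIATE_LEVELS
        return spec, levels

    def fit(self, X: pd.DataFrame, y) -> "NuisanceNormalizer":
        if self.modality_map is None:
            raise ValueError("NuisanceNormalizer requires a feature -> modality map")
        spec, levels = self._resolved_specs()
        y = np.asarray(y)
        controls = X.loc[y == self.control_class]
        if len(controls) == 0:
            raise ValueError(f"no subjects of control class {self.control_class!r}")

        self.design_specs_: dict[str, DesignSpec] = {}
        self.coef_: dict[str, np.ndarray] = {}
        self.design_means_: dict[str, np.ndarray] = {}
        for feature, modality in self.modality_map.items():
            covs = spec.get(modality, [])
            if not covs or feature not in X.columns:
                continue  # identity for this feature
            dspec = DesignSpec.build(covs, levels)
            design = dspec.matrix(controls)
            target = controls[feature].to_numpy(float)
            ok = ~np.isnan(target) & ~np.isnan(design).any(axis=1)
            n_ok = int(ok.sum())
            if n_ok <= design.shape[1]:
                logger.warning(
                    "feature %r: only %d usable control subjects for %d design columns; "
                    "feature passes through uncorrected", feature, n_ok, design.shape[1]
                )
                continue
            coef, _, rank, _ = np.linalg.lstsq(design[ok], target[ok], rcond=None)
            if rank < design.shape[1]:
                logger.warning("feature %r: rank-deficient nuisance design; "
                               "feature passes through uncorrected", feature)
                continue
            self.design_specs_[feature] = dspec
            self.coef_[feature] = coef
            self.design_means_[feature] = design[ok].mean(axis=0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "coef_"):
            raise ValueError("NuisanceNormalizer is not fitted; call fit first")
        out = X.copy()
        for feature, coef in self.coef_.items():
            if feature not in out.columns:
                continue
            design = self.design_specs_[feature].matrix(out)
            # missing covariate -> control-group mean for the affected terms
            means = self.design_means_[feature]
            nanmask = np.isnan(design)
            if nanmask.any():
                design = np.where(nanmask, np.broadcast_to(means, design.shape), design)
            expected = design @ coef
            out[feature] = out[feature].to_numpy(float) - expected  # missing stays NaN
        return out

    # ---------------------------------------------------------- persistence

    def to_dict(self) -> dict:
        if not hasattr(self, "coef_"):
            raise ValueError("NuisanceNormalizer is not fitted; call fit first")
        return {
            "control_class": self.control_class,
            "features": {
                f: {
                    "covariates": self.design_specs_[f].covariates,
                    "levels": {k: list(v) for k, v in self.design_specs_[f].levels.items()},
                    "coef": self.coef_[f].tolist(),
                    "design_means": self.design_means_[f].tolist(),
                }
                for f in self.coef_
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NuisanceNormalizer":
        norm = cls(modality_map={}, control_class=d["control_class"])
        norm.design_specs_ = {}
        norm.coef_ = {}
        norm.design_means_ = {}
        for f, spec in d["features"].items():
            norm.design_specs_[f] = DesignSpec.build(spec["covariates"], spec["levels"])
            norm.coef_[f] = np.asarray(spec["coef"], float)
            norm.design_means_[f] = np.asarray(spec["design_means"], float)
        return norm
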