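import numpy as np
import pytest

from dsindex import (
    FeatureGroup,
    FeatureHierarchy,
    FeatureLeaf,
    generate_cohort,
    preset_separable,
)

CLASSES = ["CN", "AD", "FTLD", "DLB", "VaD"]


@pytest.fixture(scope="session")
def toy_hierarchy():
    """Two modality branches, four features, one structural, one pair-restricted."""
    return FeatureHierarchy(FeatureGroup("all", [
        FeatureGroup("NP", [
            FeatureLeaf("memory", "NP"),
            FeatureLeaf("fluency", "NP"),
        ]),
        FeatureGroup("AMRI", [
            FeatureLeaf("atrophy", "AMRI", structural=True),
            FeatureLeaf("tbm_cn_ad", "AMRI", structural=True,
                        pair_restriction=frozenset({frozenset({"CN", "AD"})})),
        ]),
    ]))


@pytest.fixture(scope="session")
def small_sim_config():
    """Well-separated five-class cohort, 20 subjects per class."""
    return preset_separable(3.0, class_sizes={c: 20 for c in CLASSES}, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    cohort, _ = generate_cohort(small_sim_config)
    return cohort


@pytest.fixture(scope="session")
def small_study_config(small_sim_config):
    return small_sim_config.study_config()


def random_two_class_frame(rng, n_per_class=8, n_features=4):
    """Tiny random two-class feature table for symmetry/property checks."""
    import pandas as pd
    cols = {f"f{k}": rng.normal(rng.normal(0, 1), 1.0, size=2 * n_per_class)
            for k in range(n_features)}
    X = pd.DataFrame(cols)
    # sprinkle missingness
    mask = rng.random(X.shape) < 0.1
    X = X.mask(mask)
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return X, y
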