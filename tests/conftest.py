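import numpy as np
import pandas as pd
import pytest

from texturenet import (
    FeatureMatrix,
    FEATURE_COLUMNS,
    PhantomSpec,
    RegionTable,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230929)


@pytest.fixture
def region_table():
    """Six regions: one homologous pair (1, 2), one pair (3, 4), two solo."""
    df = pd.DataFrame(
        {
            "label_id": [1, 2, 3, 4, 5, 6],
            "name": ["L_a", "R_a", "L_b", "R_b", "mid_c", "mid_d"],
            "homolog_id": [2, 1, 4, 3, np.nan, np.nan],
            "voxel_count": [0, 0, 0, 0, 0, 0],
        }
    )
    return RegionTable(df)


@pytest.fixture
def module_spec():
    """Eight 1000-voxel regions in two texture modules (coarse vs fine)."""
    return PhantomSpec(
        layout=(2, 2, 2),
        region_shape=(10, 10, 10),
        smoothing={1: 2.5, 2: 2.5, 3: 2.5, 4: 2.5, 5: 0.0, 6: 0.0, 7: 0.0, 8: 0.0},
        modules={1: "A", 2: "A", 3: "A", 4: "A", 5: "B", 6: "B", 7: "B", 8: "B"},
        homolog_pairs=[(1, 2), (3, 4)],
        seed=7,
    )


def make_feature_matrix(values: np.ndarray, labels=None, subject="sub-x") -> FeatureMatrix:
    """Wrap an (n_regions, 55) array as a FeatureMatrix."""
    n = values.shape[0]
    labels = labels if labels is not None else list(range(1, n + 1))
    df = pd.DataFrame(values, index=labels, columns=FEATURE_COLUMNS)
    return FeatureMatrix(values=df, subject_id=subject, normalized=True)
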