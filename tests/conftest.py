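import numpy as np
import pandas as pd
import pytest

from perturbmap import (
    CountMatrix,
    ObservationMeta,
    SplatParams,
    normalize_log1p_cpm,
    simulate_dataset,
)
from perturbmap.simulate import PatternField


@pytest.fixture(scope="session")
def toy_counts() -> CountMatrix:
    values = np.array(
        [
            [5, 0, 2, 1],
            [0, 3, 0, 0],
            [1, 1, 4, 2],
        ]
    )
    return CountMatrix(values, ["g1", "g2", "g3"], ["b1", "b2", "b3", "b4"])


@pytest.fixture(scope="session")
def border_dataset():
    """Small half-border simulation with a strong effect."""
    params = SplatParams(
        n_genes=300, n_barcodes=240, de_prob=0.1, de_fac_loc=1.0, seed=7
    )
    return simulate_dataset(params, "half_border")


@pytest.fixture(scope="session")
def null_dataset():
    params = SplatParams(n_genes=300, n_barcodes=240, de_prob=0.0, seed=11)
    return simulate_dataset(params, "null")


def make_celltype_dataset(seed=3, n_genes=400, n_barcodes=360, de_fac_loc=1.0, de_prob=0.1):
    """Three pseudo cell types laid out as x-tertiles; only the first tertile
    carries differential expression between the two conditions."""
    pattern = PatternField("first_tertile", lambda x, y: (x < 1 / 3).astype(float))
    params = SplatParams(
        n_genes=n_genes,
        n_barcodes=n_barcodes,
        de_prob=de_prob,
        de_fac_loc=de_fac_loc,
        seed=seed,
    )
    dataset = simulate_dataset(params, pattern)
    x = dataset.coords.table["x"]
    cell_type = pd.cut(x, [0, 1 / 3, 2 / 3, 1.0], labels=["ct0", "ct1", "ct2"])
    meta = ObservationMeta(
        pd.DataFrame(
            {"condition": dataset.conditions, "cell_type": cell_type.astype(str)},
            index=dataset.coords.barcodes,
        )
    )
    features = normalize_log1p_cpm(dataset.counts)
    return features, meta, dataset


@pytest.fixture(scope="session")
def celltype_dataset():
    return make_celltype_dataset()
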