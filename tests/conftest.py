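import numpy as np
import pandas as pd
import pytest

from metabotyper import qc
from metabotyper import synthetic as syn
from metabotyper.tables import BiomassTable, FeatureTable


@pytest.fixture(scope="session")
def small_spec():
    return syn.DesignSpec(n_genotypes=4, n_replicates=5, n_features=150, seed=42)


@pytest.fixture(scope="session")
def small_study(small_spec):
    return syn.generate_study(small_spec)


@pytest.fixture(scope="session")
def filtered_log2(small_study):
    filt = qc.run_qc(small_study.table, small_study.blanks)
    return qc.log2_transform(filt)


def make_feature_table(values, meta_rows=None, log_scale=False):
    """Tiny FeatureTable helper: values is (n_samples, n_features) array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    idx = [f"s{i}" for i in range(n)]
    if meta_rows is None:
        meta_rows = [
            dict(plant_id=f"p{i}", genotype="G1", tissue="aboveground",
                 regime="control", replicate=i + 1)
            for i in range(n)
        ]
    meta = pd.DataFrame(meta_rows, index=idx)
    cols = [f"F{j + 1:03d}" for j in range(values.shape[1])]
    return FeatureTable(
        pd.DataFrame(values, index=idx, columns=cols), meta, log_scale=log_scale
    )


def make_biomass(rows):
    return BiomassTable(pd.DataFrame(rows))
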