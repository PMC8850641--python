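import numpy as np
import pandas as pd
import pytest

from cernet.models import CountMatrix
from cernet.simulate import SimulationConfig, simulate

DESIGN_3V3 = {
    "BH-1": "BH",
    "BH-2": "BH",
    "BH-3": "BH",
    "BN-1": "BN",
    "BN-2": "BN",
    "BN-3": "BN",
}


def make_count_matrix(counts, features=None, lengths=None, design=None):
    design = design or DESIGN_3V3
    arr = np.asarray(counts)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=features, columns=list(design))
    lengths_s = pd.Series(lengths, index=features) if lengths is not None else None
    return CountMatrix(df, design, lengths_s)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def fixture_dir(small_dataset, tmp_path_factory):
    from cernet.simulate import write_fixture

    out = tmp_path_factory.mktemp("fixture")
    write_fixture(small_dataset, out)
    return out


def read_tsv(path, **kw):
    # "null" is a meaningful token in our tables, not NA
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[], **kw)
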