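import numpy as np
import pandas as pd
import pytest

from somnet.design import make_design_manifest


@pytest.fixture(scope="session")
def default_manifest() -> pd.DataFrame:
    return make_design_manifest()


@pytest.fixture(scope="session")
def one_rep_manifest() -> pd.DataFrame:
    """13 generations x 2 population replicates x 2 sexes, one RNA rep."""
    return make_design_manifest(rna_replicates=(1,))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
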