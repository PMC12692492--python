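import warnings

import numpy as np
import pytest

from emtmet.simulate import SimConfig, gen_cnv_matrix, gen_single_cell

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_world():
    """A compact single-cell world shared across read-only tests."""
    config = SimConfig(seed=11, n_cells=600, n_genes=400,
                       n_cnv_features=400,
                       cnv_blocks=((40, 80, 0.3), (180, 220, -0.3),
                                   (320, 360, 0.3)))
    adata, meta, truth = gen_single_cell(config)
    return config, adata, meta, truth


@pytest.fixture(scope="session")
def small_cnv(small_world):
    config, _adata, _meta, truth = small_world
    return gen_cnv_matrix(truth, config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
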