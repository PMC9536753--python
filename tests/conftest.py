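import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from regnetrank import synthetic as gsyn


@pytest.fixture(scope="session")
def small_design():
    """A reduced two-lineage design used for fast end-to-end tests."""
    return gsyn.make_design(
        n_lineages=2,
        cells_per_lineage=3,
        n_tfs=12,
        n_genes=60,
        drivers_per_lineage=2,
        n_constitutive=2,
        n_memory=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_dataset")
    truth = gsyn.emit_dataset(small_design, outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def desk_design():
    return gsyn.make_design(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
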