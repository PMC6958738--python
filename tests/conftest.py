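import numpy as np
import pandas as pd
import pytest

from stsig.synthetic import SimConfig, simulate
from stsig import workflow

#: A scaled-down scene used by most integration-style tests: 3 sections of a
#: 12 x 10 array, 60 genes, 5 markers per class. Filter thresholds are scaled
#: with it (the defaults assume transcriptome-scale feature counts).
SMALL_CONFIG = SimConfig(
    seed=7,
    n_datasets=3,
    grid_width=12,
    grid_height=10,
    n_genes=60,
    n_signature_per_class=5,
)

SMALL_FILTER = dict(min_spot_counts=30, min_spot_features=20, min_tc_spots=2)


@pytest.fixture(scope="session")
def small_scene():
    return simulate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_pipeline(small_scene):
    reads = pd.concat(small_scene.reads.values(), ignore_index=True)
    result = workflow.reads_to_matrix(reads, small_scene.genes)
    result.sim = small_scene
    result.labels = small_scene.labels_series
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
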