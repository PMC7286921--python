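import numpy as np
import pytest

from oisiwc import preproc
from oisiwc.synthdata import SynthConfig, generate_block_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Full-length (9-epoch) two-hemisphere block dataset at 100 Hz."""
    cfg = SynthConfig(rng_seed=11)
    healthy, stroke, schedule, truth = generate_block_dataset(cfg)
    return cfg, healthy, stroke, schedule, truth


@pytest.fixture(scope="session")
def dataset_10hz(default_dataset):
    """The same dataset temporally averaged to the 10 Hz analysis rate."""
    cfg, healthy, stroke, schedule, truth = default_dataset
    return (cfg,
            preproc.temporal_average(healthy, 10),
            preproc.temporal_average(stroke, 10),
            schedule, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
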