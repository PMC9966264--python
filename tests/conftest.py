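import numpy as np
import pytest

import ramanheal as rh

#: Reduced acquisition design used by most unit tests: two groups with
#: opposite healing behaviour, first/last observation day, one mouse,
#: a handful of points — enough structure for every pipeline stage.
TINY_DESIGN = rh.CohortDesign(
    groups=("control", "ALA4"), days=(1, 14), mice=1, points=3,
    healthy_per_group=6,
)


@pytest.fixture(scope="session")
def tiny_cfg() -> rh.SyntheticConfig:
    return rh.SyntheticConfig(seed=11, design=TINY_DESIGN)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    """(SpectrumSet, truth DataFrame) for the reduced design."""
    return rh.generate_cohort_with_truth(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_clean_cohort():
    """Noise- and spike-free cohort on the reduced design."""
    cfg = rh.SyntheticConfig(seed=11, design=TINY_DESIGN,
                             noise_sd=0.0, spike_rate=0.0)
    return rh.generate_cohort_with_truth(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
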