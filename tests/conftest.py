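import numpy as np
import pytest

import bcgapnea as bg


@pytest.fixture(scope="session")
def small_model():
    """8-subject (2 per class), half-hour synthetic cohort: the workhorse
    for classifier/pipeline tests."""
    cfg = bg.PipelineConfig(tune_budget=5)
    return bg.BcgCohortModel.from_simulation(n_per_class=2, duration_h=0.5,
                                             seed=11, config=cfg)


@pytest.fixture(scope="session")
def small_results(small_model):
    return small_model.fit()


@pytest.fixture(scope="session")
def full_model():
    """The default study-scale cohort: 32 subjects, 8 per severity class,
    1 h recordings (random-search budget 10 to keep the run cheap)."""
    cfg = bg.PipelineConfig(tune_budget=10)
    return bg.BcgCohortModel.from_simulation(n_per_class=8, duration_h=1.0,
                                             seed=1, config=cfg)


@pytest.fixture(scope="session")
def full_results(full_model):
    return full_model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
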