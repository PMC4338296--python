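import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import oxbsarray as ox

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A modest calibrated dataset shared by tests that only read it."""
    cfg = ox.sim.SimConfig(n_probes=4000, seed=11)
    return ox.sim.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_run(small_dataset):
    """Preprocessed betas + test results + estimates for the shared dataset."""
    bm, mask = ox.preprocess.preprocess_dataset(small_dataset, swan_seed=11)
    results, fit = ox.diffmeth.test_probes(bm)
    estimates = ox.quantify.estimate_levels(bm, results)
    return {"bm": bm, "mask": mask, "results": results, "fit": fit, "estimates": estimates}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
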