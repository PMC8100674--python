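import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default 55-pair synthetic cohort, written to disk once."""
    from mmckit.simulate import SimulationConfig, simulate_cohort

    bundle = simulate_cohort(SimulationConfig(), np.random.default_rng(42))
    outdir = tmp_path_factory.mktemp("cohort")
    paths = bundle.write(outdir)
    return bundle, paths
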