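import pytest
from hypothesis import HealthCheck, settings

from mycobarcode.pipeline import run_all
from mycobarcode.scheme import demo_scheme_path, load_scheme
from mycobarcode.simulate import SimConfig, simulate_run

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scheme():
    return load_scheme(demo_scheme_path())


@pytest.fixture(scope="session")
def zero_noise_run(scheme, tmp_path_factory):
    """16 specimens, no sequencing error, no chimeras, no contamination."""
    cfg = SimConfig(
        n_specimens=16,
        depth_mean=100,
        error_scale=0.0,
        chimera_rate=0.0,
        contamination_rate=0.0,
        seed=7,
    )
    return simulate_run(scheme, cfg, tmp_path_factory.mktemp("sim_clean"))


@pytest.fixture(scope="session")
def default_run(scheme, tmp_path_factory):
    """100 specimens at the default noise rates, depth mean 200, seed 1."""
    cfg = SimConfig(n_specimens=100, depth_mean=200, seed=1)
    return simulate_run(scheme, cfg, tmp_path_factory.mktemp("sim_default"))


@pytest.fixture(scope="session")
def default_results(scheme, default_run, tmp_path_factory):
    """Full pipeline output for the default simulation."""
    out = tmp_path_factory.mktemp("pipe_default")
    summary, results = run_all(
        scheme, default_run.sheet_path, default_run.pool_fastqs, out
    )
    return summary, results
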