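import matplotlib
import pytest

matplotlib.use("Agg")

from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_bound():
    """One noiseless membrane-bound bacterium event with its ground truth."""
    from uptakequant import synthetic as syn

    return syn.generate_event("bound", noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_internalized():
    from uptakequant import synthetic as syn

    return syn.generate_event("internalized", noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_empty():
    from uptakequant import synthetic as syn

    return syn.generate_event("no_particle", noise_sd=0.0, seed=11)
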