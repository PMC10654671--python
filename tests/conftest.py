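import pytest
from hypothesis import settings

from methanocycle.simulate import default_config, generate, study_scale_config

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_bundle():
    """Two-site, 60-MAG noise-free community with every guild class planted."""
    return generate(default_config(seed=11, n_sites=2, n_mags=60))


@pytest.fixture(scope="session")
def study_bundle():
    """Synthetic eight-site landfill emulation (1647 MAGs)."""
    return generate(study_scale_config(seed=7))
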