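import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def single_section():
    """One small upper-hypocotyl-like section, clean signal."""
    from phytosync.synthetic import GeneratorConfig, SectionProfile

    sp = SectionProfile("upper_hypocotyl", 6, 24.0, 0.5, 51.2, 1.1, (5.0, 6.5))
    return GeneratorConfig(
        sections=[sp],
        t_start=29.0,
        t_end=150.0,
        sampling_interval=1.0,
        noise_sd=0.0,
        amplitude_cv=0.0,
        rng_seed=7,
    )
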