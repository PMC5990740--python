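import warnings

import pytest

import enamelgrowth as eg


@pytest.fixture(scope="session")
def basic_section():
    """Constant 20 um/d extension, 1.5 um/d secretion, 10 days, R=2."""
    cfg = eg.SectionConfig(cer_schedule=20.0, dsr_schedule=1.5, n_days=10,
                           edj_length=230.0, repeat_interval=2,
                           dentine_rate=11.9, seed=0)
    return eg.simulate_section(cfg)


@pytest.fixture(scope="session")
def jittered_section():
    cfg = eg.SectionConfig(cer_schedule=20.0, dsr_schedule=1.5, n_days=10,
                           edj_length=230.0, repeat_interval=2,
                           dentine_rate=11.9, jitter_sd=0.2, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return eg.simulate_section(cfg)


@pytest.fixture(scope="session")
def cynodont_section():
    """Diademodon-like preset: 88.3 um/d extension, repeat interval 2."""
    return eg.simulate_section(eg.cynodont_section_config())
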