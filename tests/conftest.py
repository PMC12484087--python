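import pytest

from photodipole import default_config


@pytest.fixture(scope="session")
def cfg():
    """Packaged default configuration (frozen dataclasses; safe to share)."""
    return default_config()


@pytest.fixture(scope="session")
def dual_result(cfg):
    from photodipole import run_dual_pathway

    return run_dual_pathway(cfg)


@pytest.fixture(scope="session")
def sweep_result(cfg):
    from photodipole import run_vr_sweep

    return run_vr_sweep(cfg)


@pytest.fixture(scope="session")
def polarity_result(cfg):
    from photodipole import run_polarity_panel

    return run_polarity_panel(cfg)
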