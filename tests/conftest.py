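import numpy as np
import pytest

from ojipsuite import synthetic as syn


@pytest.fixture
def clean_pf_spec():
    """The worked noise-free OJIP example: F_o=500, F_m=2500, V_J=0.5, V_I=0.8."""
    return syn.PfSpec(f_o=500.0, f_m=2500.0, v_J=0.5, v_I=0.8)


@pytest.fixture
def clean_pf_trace(clean_pf_spec):
    return syn.make_pf_trace(clean_pf_spec)


@pytest.fixture
def mr_valley_spec():
    """Valley with closed-form minimum at 8 * ln(78/8) ~ 18.22 ms."""
    return syn.MrSpec(amplitude=0.05, tau_ox_ms=8.0, tau_red_ms=70.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
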