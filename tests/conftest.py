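import numpy as np
import pytest

from sonoquant.phantom import (
    DEFAULT_VESSEL_NOISE,
    DiameterWaveform,
    PhantomTruth,
    make_coupled_vessel,
    make_vessel_cine,
)


@pytest.fixture(scope="session")
def noiseless_vessel():
    """Noiseless pulsating vessel, Dd=1.0 Ds=1.2 mm, with reference trace."""
    truth = PhantomTruth(seed=1, diameter=DiameterWaveform(dd_mm=1.0, ds_mm=1.2))
    loop, ref = make_vessel_cine(truth)
    return truth, loop, ref


@pytest.fixture(scope="session")
def static_vessel():
    truth = PhantomTruth(seed=2, diameter=DiameterWaveform(dd_mm=1.0, ds_mm=1.0))
    loop, ref = make_vessel_cine(truth)
    return truth, loop, ref


@pytest.fixture(scope="session")
def noisy_vessel():
    truth = PhantomTruth(seed=1, diameter=DiameterWaveform(dd_mm=1.0, ds_mm=1.2),
                         noise=DEFAULT_VESSEL_NOISE)
    loop, ref = make_vessel_cine(truth)
    return truth, loop, ref


@pytest.fixture(scope="session")
def coupled_noiseless():
    """Coupled vessel + Doppler phantom, PWV_true = 2.0 m/s, noiseless."""
    truth = PhantomTruth(seed=1, true_pwv_m_s=2.0,
                         diameter=DiameterWaveform(dd_mm=1.0, ds_mm=1.2))
    loop, spec, dref, vref = make_coupled_vessel(truth)
    return truth, loop, spec, dref, vref


@pytest.fixture
def rng():
    return np.random.default_rng(0)
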