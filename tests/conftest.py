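import numpy as np
import pytest

from bksensor.mwc import PhysicalConstants, TenStateRates
from bksensor.qmatrix import ChannelEnsemble, Waveform, macroscopic_current, propagate, stationary_distribution
from bksensor.synthetic import UncagingTransientSpec, gen_uncaging_transient


@pytest.fixture(scope="session")
def constants():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def rates():
    return TenStateRates()


@pytest.fixture(scope="session")
def ensemble():
    return ChannelEnsemble(n=1662, g_single=258.0, e_rev=-80.0)


@pytest.fixture(scope="session")
def uncaging_spec():
    return UncagingTransientSpec(t_flash=5.0)


def simulate_flash_current(rates, constants, ensemble, spec, v_mV, t_end=58.0, dt_max=0.02):
    """Forward-simulate the whole-cell current evoked by a flash at fixed V."""
    t = np.arange(0.0, t_end + 1e-9, 0.02)
    ca = gen_uncaging_transient(spec, t)
    vw = Waveform(np.array([0.0, t_end]), np.array([v_mV, v_mV], float), "voltage")
    p0 = stationary_distribution(rates.generator(constants, v_mV, spec.ca_base))
    traj = propagate(rates, constants, vw, ca, p0, dt_max=dt_max)
    return macroscopic_current(traj, ensemble, vw), ca


@pytest.fixture(scope="session")
def flash_current_30mV(rates, constants, ensemble, uncaging_spec):
    """Flash-evoked current at the +30 mV reference voltage, with its Ca input."""
    return simulate_flash_current(rates, constants, ensemble, uncaging_spec, 30.0)
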