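import numpy as np
import pytest

from emulrelax import BPPContext, SignalTrace


@pytest.fixture
def ctx_unit():
    """15 MHz context with unit dipolar prefactor."""
    return BPPContext(dipolar_prefactor_K=1.0)


@pytest.fixture
def ctx_bare():
    """15 MHz context without a dipolar prefactor (ratio-only work)."""
    return BPPContext()


def make_cpmg(t21=0.03, t22=0.3, p=0.2, n=200, noise=None, seed=0):
    """Biexponential CPMG trace on a log-spaced echo grid."""
    times = np.geomspace(0.1 * t21, 4 * t22, n)
    amps = p * np.exp(-times / t21) + (1 - p) * np.exp(-times / t22)
    sigma = None
    if noise is not None:
        rng = np.random.default_rng(seed)
        amps = amps + rng.normal(0.0, noise, size=amps.shape)
        sigma = noise
    return SignalTrace(times, amps, "cpmg", noise_sigma=sigma)


def make_ir(t11=0.06, t12=0.6, p=0.2, n=32, noise=None, seed=0):
    """Biexponential inversion-recovery trace on a log-spaced delay grid."""
    times = np.geomspace(0.1 * t11, 4 * t12, n)
    amps = 1.0 - 2.0 * (p * np.exp(-times / t11) + (1 - p) * np.exp(-times / t12))
    sigma = None
    if noise is not None:
        rng = np.random.default_rng(seed)
        amps = amps + rng.normal(0.0, noise, size=amps.shape)
        sigma = noise
    return SignalTrace(times, amps, "inversion_recovery", noise_sigma=sigma)
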