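import numpy as np
import pytest

from amperofit import AmperogramTrace, ExpDecayParams, FitWindow, model_current


def make_window(A, B, C, n=15, dt=1.0, noise=0.0, seed=0):
    """Noiseless (or noisy) fit window sampled from the decay model."""
    t = np.arange(n) * dt
    y = model_current(t, ExpDecayParams(A, B, C))
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise, n)
    return FitWindow(t=t, y=y)


def plateau_decay_trace(A=10.0, B=0.1, C=2.0, plateau=100, n_decay=100, dt=1.0,
                        noise=0.0, seed=0):
    """Flat plateau at A+C followed by a clean exponential decay."""
    n = plateau + n_decay
    t = np.arange(n) * dt
    y = np.empty(n)
    y[:plateau] = A + C
    y[plateau:] = model_current(t[:n_decay], ExpDecayParams(A, B, C))
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise, n)
    return AmperogramTrace(times=t, currents=y, dt=dt)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
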