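import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dnoekit import SampleRates, Schedule
from dnoekit.scheduler import DSAT_GRID_11

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sample_rates():
    """Sample-level rates typical for a small protein at high field."""
    return SampleRates(
        r1w=0.412,
        r1h=0.85,
        r1n={"D58": 1.4, "R74": 1.2, "G76": 1.1},
        r1n_sd={"D58": 0.008, "R74": 0.008, "G76": 0.008},
        k_exchange=5.0,
    )


@pytest.fixture
def dnoe_schedule():
    """An adequate DNOE schedule using the full validated delay grid."""
    return Schedule(rd1=13.0, rd2=13.0, dsat=DSAT_GRID_11, b0=22.3)


def rk4_pool_oracle(sys_, t_end, h, saturate_h=False, saturate_w=False, initial=None):
    """Brute-force fixed-step RK4 integrator of the three-pool ODE.

    Independent of the eigen-decomposition propagator: integrates
    dM/dt = -L (M - M_eq) directly, clamping saturated pools to zero.
    """
    eq = sys_.eq_mags
    L = sys_.relaxation_matrix()
    m = eq.copy() if initial is None else np.array(initial, dtype=float)
    clamp = [i for i, on in ((1, saturate_h), (2, saturate_w)) if on]

    def f(state):
        d = -(L @ (state - eq))
        d[clamp] = 0.0
        return d

    m[clamp] = 0.0
    n_steps = int(round(t_end / h))
    for _ in range(n_steps):
        k1 = f(m)
        k2 = f(m + 0.5 * h * k1)
        k3 = f(m + 0.5 * h * k2)
        k4 = f(m + h * k3)
        m = m + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        m[clamp] = 0.0
    return m
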