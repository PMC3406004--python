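import numpy as np
import pytest

from cocainepk import (
    ENZYME_PANEL,
    REFERENCE_PK_PARAMS,
    EnzymeKinetics,
)


@pytest.fixture(scope="session")
def ref_params():
    return REFERENCE_PK_PARAMS


@pytest.fixture(scope="session")
def wtbche():
    return ENZYME_PANEL["wtBChE"]


@pytest.fixture(scope="session")
def coch3():
    return ENZYME_PANEL["CocH3"]


@pytest.fixture(scope="session")
def no_enzyme():
    """Enzyme with zero active-site concentration: v_max = 0."""
    return EnzymeKinetics("inert", k_cat=1.0, K_M=1.0, E_conc=0.0)


def rk4_simulate(params, enzyme, c1_0, t_end, dt=0.001):
    """Fixed-step classical Runge-Kutta integrator: the brute-force oracle.

    Independent of the package's adaptive solver path; shares only the model
    definition.  Returns (t, C1, C2) sampled at every step.
    """
    vmax, km = enzyme.v_max, enzyme.K_M
    kpb, kbp, r = params.K_pb, params.K_bp, params.V_p / params.V_b

    def f(c1, c2):
        d1 = -vmax * c1 / (km + c1) - kpb * c1 + kbp * c2
        d2 = r * (kpb * c1 - kbp * c2)
        return d1, d2

    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    c1 = np.empty(n + 1)
    c2 = np.empty(n + 1)
    c1[0], c2[0] = c1_0, 0.0
    x, y = c1_0, 0.0
    for i in range(1, n + 1):
        k1 = f(x, y)
        k2 = f(x + 0.5 * dt * k1[0], y + 0.5 * dt * k1[1])
        k3 = f(x + 0.5 * dt * k2[0], y + 0.5 * dt * k2[1])
        k4 = f(x + dt * k3[0], y + dt * k3[1])
        x += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        y += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        c1[i], c2[i] = x, y
    return t, c1, c2
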