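import numpy as np
import pytest

from powderlaw.encoding import sphere_quadrature
from powderlaw.gaussian import CompartmentParams


def quadrature_powder_oracle(b, b_delta, d_par, d_perp, degree=61):
    """Independent sphere-average oracle for the closed-form powder signal.

    Averages exp(-tr(B D(n))) over compartment orientations n with a dense
    spherical quadrature; tr(B D(n)) = b*d_perp + (d_par - d_perp) *
    (b(1-b_delta)/3 + b*b_delta*(g.n)^2) with g = e_z.
    """
    pts, wts = sphere_quadrature(degree)
    t2 = pts[:, 2] ** 2
    diff = d_par - d_perp
    tr = b * d_perp + diff * (b * (1.0 - b_delta) / 3.0 + b * b_delta * t2)
    return float((wts * np.exp(-tr)).sum() / (4.0 * np.pi))


def pte_series_oracle(bD, n_terms=200):
    """Taylor-series oracle for the planar stick signal, independent of the
    Dawson-function evaluation path:
    S = sqrt(pi) e^{-x^2} erfi(x) / (2x), erfi(x) = (2/sqrt(pi)) *
    sum_k x^(2k+1) / (k! (2k+1)), x = sqrt(bD/2).
    """
    x = np.sqrt(bD / 2.0)
    if x == 0:
        return 1.0
    term = x
    s = term / 1.0
    for k in range(1, n_terms):
        term = term * x * x / k
        s += term / (2 * k + 1)
    return float(np.exp(-(x**2)) * s / x)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_compartments(rng):
    """200 random (b, b_delta, D_par, D_perp) draws spanning the supported
    parameter ranges."""
    n = 200
    b = rng.uniform(0.0, 10.0, n)
    b_delta = rng.uniform(-0.5, 1.0, n)
    d_par = rng.uniform(0.0, 3.0, n)
    d_perp = rng.uniform(0.0, 1.0, n) * d_par
    return list(zip(b, b_delta, d_par, d_perp))


@pytest.fixture(scope="session")
def small_pte_protocol():
    from powderlaw.encoding import build_protocol

    return build_protocol("sim21", b_delta=-0.5, seed=0)


@pytest.fixture(scope="session")
def default_params():
    return CompartmentParams(D_par=2.0, D_perp=0.0)
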