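"""Closed-form Gaussian-compartment signals under axisymmetric b-tensors.

The powder (direction) average of an axially symmetric Gaussian compartment
with diffusivities (D_par, D_perp) measured with a b-tensor of size b and
shape b_delta is

    S = sqrt(pi) * exp(-(b/3)(D_par + 2 D_perp - b_delta (D_par - D_perp)))
        * erf(sqrt(z)) / (2 sqrt(z)),        z = b * b_delta * (D_par - D_perp).

For z < 0 the error function becomes imaginary; the signal is then evaluated
overflow-free through the Dawson function D(y) via
erfi(y) = 2 exp(y^2) D(y) / sqrt(pi):

    S = exp(-E + y^2) * D(y) / y,            y = sqrt(-z),

and near z = 0 a fourth-order series keeps the two branches continuous.
All b are ms/um^2 and diffusivities um^2/ms, so b*D is dimensionless.

The planar-encoding (b_delta = -1/2) stick signal admits the asymptotic
expansion S ~ (1/bD) * sum_k (2k-1)!! / (bD)^k, whose truncation order N must
stay at or below floor(bD) (the series is asymptotic, not convergent).
A power-law decay S ~ b^(-alpha) at large b exists only for three encoding /
geometry pairings: LTE sticks (alpha = 1/2), PTE sticks (alpha = 1) and LTE
pancakes (alpha = 1); every other combination decays exponentially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import dawsn, erf

from .encoding import _check_bdelta

__all__ = [
    "CompartmentParams",
    "AsymptoticApprox",
    "compartment_signal_direction",
    "powder_signal",
    "log_powder_signal",
    "ste_signal",
    "pte_stick_signal",
    "pte_asymptotic",
    "normalized_error",
    "min_terms_table",
    "powerlaw_condition",
]

#: |z| below which the series kernel replaces the erf/Dawson branches.
_SERIES_EPS = 1e-4


@dataclass(frozen=True)
class CompartmentParams:
    """Axially symmetric Gaussian compartment (diffusivities in um^2/ms)."""

    D_par: float
    D_perp: float = 0.0

    def __post_init__(self):
        if self.D_par < 0 or self.D_perp < 0:
            raise ValueError("diffusivities must be nonnegative")


def _params(params) -> tuple[float, float]:
    if isinstance(params, CompartmentParams):
        return params.D_par, params.D_perp
    d_par, d_perp = params
    if d_par < 0 or d_perp < 0:
        raise ValueError("diffusivities must be nonnegative")
    return float(d_par), float(d_perp)


def compartment_signal_direction(btensor, params, axis) -> float:
    """exp(-tr(B D)) for one encoding and one compartment orientation.

    D = axis axis^T (D_par - D_perp) + D_perp I.  ``btensor`` may be an
    AxisymmetricBTensor or a plain 3x3 matrix.
    """
    d_par, d_perp = _params(params)
    B = btensor.matrix if hasattr(btensor, "matrix") else np.asarray(btensor, float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    tr_bd = d_perp * np.trace(B) + (d_par - d_perp) * (axis @ B @ axis)
    return float(np.exp(-tr_bd))


def _log_kernel(z: np.ndarray) -> np.ndarray:
    """log of sqrt(pi) erf(sqrt(z)) / (2 sqrt(z)), continued to z < 0.

    For z < 0 the value returned is log(exp(y^2) D(y)/y) = y^2 + log(D(y)/y),
    y = sqrt(-z), i.e. the imaginary-error-function continuation.
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z > _SERIES_EPS
    neg = z < -_SERIES_EPS
    mid = ~(pos | neg)
    if np.any(pos):
        rz = np.sqrt(z[pos])
        out[pos] = np.log(np.sqrt(np.pi) * erf(rz) / (2.0 * rz))
    if np.any(neg):
        y = np.sqrt(-z[neg])
        out[neg] = y * y + np.log(dawsn(y) / y)
    if np.any(mid):
        zm = z[mid]
        # sqrt(pi) erf(sqrt(z))/(2 sqrt(z)) = 1 - z/3 + z^2/10 - z^3/42 + z^4/216
        out[mid] = np.log1p(
            zm * (-1.0 / 3.0 + zm * (0.1 + zm * (-1.0 / 42.0 + zm / 216.0)))
        )
    return out


def log_powder_signal(b, b_delta: float, params) -> np.ndarray:
    """Natural log of the powder-averaged compartment signal (stable at
    arbitrarily strong weighting)."""
    _check_bdelta(b_delta)
    d_par, d_perp = _params(params)
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be nonnegative")
    diff = d_par - d_perp
    exponent = b / 3.0 * (d_par + 2.0 * d_perp - b_delta * diff)
    z = b * b_delta * diff
    return -exponent + _log_kernel(z)


def powder_signal(b, b_delta: float, params):
    """Powder-averaged signal fraction of one Gaussian compartment.

    ``params`` is a CompartmentParams or a (D_par, D_perp) pair; ``b`` may be
    scalar or array (ms/um^2).  Returns values in (0, 1], equal to 1 at b=0.
    """
    out = np.exp(log_powder_signal(b, b_delta, params))
    return float(out) if np.isscalar(b) or np.ndim(b) == 0 else out


def ste_signal(b, params):
    """Spherical-encoding (b_delta = 0) signal: exp(-b (D_par + 2 D_perp)/3)."""
    d_par, d_perp = _params(params)
    b = np.asarray(b, dtype=float)
    out = np.exp(-b * (d_par + 2.0 * d_perp) / 3.0)
    return float(out) if out.ndim == 0 else out


def pte_stick_signal(bD):
    """Exact planar-encoding powder-averaged stick signal vs dimensionless bD.

    S = sqrt(pi) e^{-bD/2} erfi(sqrt(bD/2)) / (2 sqrt(bD/2)) = D(x)/x with
    x = sqrt(bD/2) (Dawson form; no overflow at any bD).
    """
    bD = np.asarray(bD, dtype=float)
    if np.any(bD < 0):
        raise ValueError("bD must be nonnegative")
    x = np.sqrt(bD / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(x < 1e-8, 1.0 - bD / 3.0, dawsn(x) / np.where(x == 0, 1.0, x))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AsymptoticApprox:
    """Truncated large-bD expansion of the PTE stick signal."""

    N: int
    bD: float
    value: float
    normalized_error: float


def pte_asymptotic(bD: float, N: int) -> AsymptoticApprox:
    """(1/bD) sum_{k=0..N} (2k-1)!! / bD^k, with (-1)!! = 1 (k = 0 term 1/bD).

    Divergent for fixed bD as N grows; meaningful only for N <= floor(bD).
    """
    if bD <= 0:
        raise ValueError("bD must be positive")
    if N < 0:
        raise ValueError("N must be >= 0")
    term, total = 1.0, 1.0
    for k in range(1, N + 1):
        term *= (2 * k - 1) / bD
        total += term
    value = total / bD
    exact = pte_stick_signal(bD)
    return AsymptoticApprox(
        N=N, bD=float(bD), value=value, normalized_error=abs(exact - value) / exact
    )


def normalized_error(s_exact: float, s_approx: float) -> float:
    """|S - S_hat| / S for comparing exact and approximated signals."""
    if s_exact <= 0:
        raise ValueError("exact signal must be positive")
    return abs(s_exact - s_approx) / s_exact


def min_terms_table(bD_grid, thresholds) -> pd.DataFrame:
    """Minimum truncation order N meeting each error threshold, per bD.

    The search runs N = 0..floor(bD); NaN marks thresholds no admissible N
    reaches (the asymptotic series cannot be pushed further).  Rows are
    thresholds, columns bD values.
    """
    bD_grid = np.asarray(bD_grid, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(bD_grid <= 0):
        raise ValueError("bD grid must be positive")
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    table = np.full((len(thresholds), len(bD_grid)), np.nan)
    for j, bD in enumerate(bD_grid):
        errs = np.array(
            [pte_asymptotic(bD, n).normalized_error for n in range(int(np.floor(bD)) + 1)]
        )
        for i, thr in enumerate(thresholds):
            ok = np.nonzero(errs <= thr)[0]
            if ok.size:
                table[i, j] = ok[0]
    return pd.DataFrame(table, index=thresholds, columns=bD_grid)


def powerlaw_condition(b_delta: float, D_par: float, D_perp: float, tol: float = 1e-9):
    """Does the powder-averaged signal follow a power law at large b?

    Exactly three pairings qualify; everything else is exponentially
    suppressed.  Returns (exists, alpha-or-None).
    """
    _check_bdelta(b_delta)
    if D_par < 0 or D_perp < 0:
        raise ValueError("diffusivities must be nonnegative")
    stick = abs(D_perp) <= tol and D_par > tol
    pancake = abs(D_par) <= tol and D_perp > tol
    if abs(b_delta - 1.0) <= tol and stick:
        return True, 0.5
    if abs(b_delta + 0.5) <= tol and stick:
        return True, 1.0
    if abs(b_delta - 1.0) <= tol and pancake:
        return True, 1.0
    return False, None
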