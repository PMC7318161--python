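"""Restricted (non-Gaussian) compartments: cylinders, spheres, and the dot.

Finite-radius restrictions are handled in the Gaussian phase approximation
(GPA): for a pulsed-gradient pair of width delta and separation Delta the
log-attenuation perpendicular to an impermeable cylinder of radius r is a
Bessel-root series (van Gelderen form).  We map it to an effective
perpendicular diffusivity

    D_perp_eff = -ln(E_perp) / b_unit,   b_unit = (gamma g delta)^2 (Delta - delta/3) = 1,

which then composes with any axisymmetric b-tensor through the closed-form
powder average: the cylinder behaves as a Gaussian compartment with
(D_par, D_perp_eff) at the protocol timing.  Spheres are isotropic, so their
attenuation is exp(-b D_sph_eff) independent of b-tensor shape and direction;
a zero-radius sphere is the "dot" (still water), contributing a constant
signal offset.

Axon-radius heterogeneity enters by averaging the cylinder signal over a
radius histogram with volume (r^2) weights, after scaling the histology
radii by a shrinkage factor eta (eta = 0 collapses every axon to a stick).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import jnp_zeros, spherical_jn
from scipy.stats import lognorm

from .encoding import Timing
from .gaussian import powder_signal, pte_stick_signal

__all__ = [
    "RadiusHistogram",
    "SphereParams",
    "cylinder_perp_diffusivity",
    "sphere_effective_diffusivity",
    "cylinder_powder_signal",
    "sphere_signal",
    "radius_weighted_average",
    "default_radius_histogram",
]

#: convergence guard: the last retained series term may not exceed this
#: fraction of the partial sum.
_SERIES_GUARD = 1e-3


@dataclass(frozen=True)
class RadiusHistogram:
    """Axon-radius histogram: bin centres (um), weights, shrinkage eta."""

    radii: np.ndarray
    counts: np.ndarray
    eta: float = 1.0

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if r.shape != c.shape:
            raise ValueError("radii and counts must have matching shapes")
        if np.any(r < 0) or np.any(c < 0):
            raise ValueError("radii and counts must be nonnegative")
        if c.sum() <= 0:
            raise ValueError("histogram counts must sum to > 0")
        if self.eta < 0:
            raise ValueError("shrinkage eta must be nonnegative")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "counts", c)

    @property
    def effective_radii(self) -> np.ndarray:
        return self.eta * self.radii


@dataclass(frozen=True)
class SphereParams:
    """Restricted sphere; R_s = 0 denotes the dot compartment."""

    R_s: float = 8.0
    D0: float = 2.0

    def __post_init__(self):
        if self.R_s < 0:
            raise ValueError("R_s must be nonnegative")
        if self.D0 <= 0:
            raise ValueError("D0 must be positive")


@lru_cache(maxsize=8)
def _cylinder_roots(n_roots: int) -> tuple:
    """First n roots of J1'(x) = 0."""
    return tuple(jnp_zeros(1, n_roots))


@lru_cache(maxsize=8)
def _sphere_roots(n_roots: int) -> tuple:
    """First n roots of j1'(x) = 0 (spherical Bessel derivative)."""

    def j1p(x):
        return spherical_jn(1, x, derivative=True)

    roots = []
    m = 1
    lo = 0.5
    while len(roots) < n_roots:
        hi = (m + 0.5) * np.pi
        if j1p(lo) * j1p(hi) < 0:
            roots.append(brentq(j1p, lo, hi, xtol=1e-14))
            lo = hi
        else:  # scan forward in small steps (defensive; brackets are regular)
            xs = np.linspace(lo, hi, 64)
            vals = j1p(xs)
            sign_change = np.nonzero(vals[:-1] * vals[1:] < 0)[0]
            for k in sign_change:
                roots.append(brentq(j1p, xs[k], xs[k + 1], xtol=1e-14))
                if len(roots) >= n_roots:
                    break
            lo = hi
        m += 1
    return tuple(roots[:n_roots])


def _gpa_waveform_factor(lam: np.ndarray, delta: float, Delta: float) -> np.ndarray:
    """Closed-form double time integral of the PGSE pair against exp(-lam |t1-t2|).

    Equals 2*lam*delta - 2 + 2 e^{-lam delta} + 2 e^{-lam Delta}
    - e^{-lam (Delta-delta)} - e^{-lam (Delta+delta)}; -> lam^3 delta^2
    (Delta - delta/3) as lam -> 0 (free diffusion).
    """
    return (
        2.0 * lam * delta
        - 2.0
        + 2.0 * np.exp(-lam * delta)
        + 2.0 * np.exp(-lam * Delta)
        - np.exp(-lam * (Delta - delta))
        - np.exp(-lam * (Delta + delta))
    )


def _gpa_effective_diffusivity(
    r: float, timing: Timing, roots: np.ndarray, geom_offset: float
) -> float:
    """Shared cylinder/sphere GPA series -> effective diffusivity.

    geom_offset is 1 for cylinders (denominator mu^2 - 1, roots of J1') and
    2 for spheres (mu^2 - 2, roots of j1').
    """
    if r == 0:
        return 0.0
    D0, delta, Delta = timing.D0, timing.delta, timing.Delta
    mu = np.asarray(roots)
    alpha2 = (mu / r) ** 2  # 1/um^2
    lam = D0 * alpha2  # 1/ms
    terms = 2.0 * _gpa_waveform_factor(lam, delta, Delta) / (
        D0**2 * alpha2**3 * (mu**2 - geom_offset)
    )
    total = terms.sum()
    if abs(terms[-1]) > _SERIES_GUARD * abs(total):
        raise RuntimeError(
            "GPA Bessel-root series not converged; increase n_roots "
            f"(last term fraction {abs(terms[-1] / total):.2e})"
        )
    d_eff = total / (delta**2 * (Delta - delta / 3.0))
    return float(min(max(d_eff, 0.0), D0))


def cylinder_perp_diffusivity(
    r: float, D0: float = 2.0, delta: float = 15.0, Delta: float = 30.0, n_roots: int = 20
) -> float:
    """Effective perpendicular diffusivity (um^2/ms) of an impermeable
    cylinder of radius r (um) under a pulsed-gradient pair.

    Monotone in r, 0 at r = 0 (stick), -> D0 as r^2 >> D0*Delta (free).
    """
    if r < 0:
        raise ValueError("radius must be nonnegative")
    timing = Timing(delta=delta, Delta=Delta, D0=D0)
    return _gpa_effective_diffusivity(r, timing, np.array(_cylinder_roots(n_roots)), 1.0)


def sphere_effective_diffusivity(sphere: SphereParams, timing: Timing, n_roots: int = 20) -> float:
    """Effective isotropic diffusivity of a restricted sphere at the
    protocol timing; 0 for the dot (R_s = 0)."""
    t = Timing(delta=timing.delta, Delta=timing.Delta, D0=sphere.D0)
    return _gpa_effective_diffusivity(sphere.R_s, t, np.array(_sphere_roots(n_roots)), 2.0)


def cylinder_powder_signal(b, b_delta: float, D_par: float, r: float, timing: Timing):
    """Powder-averaged signal of a dispersed cylinder population of one
    radius: the Gaussian closed form with D_perp_eff(r).  r = 0 reduces to
    the stick results (e.g. the Dawson form for planar encoding)."""
    d_perp = cylinder_perp_diffusivity(r, D0=timing.D0, delta=timing.delta, Delta=timing.Delta)
    return powder_signal(b, b_delta, (D_par, d_perp))


def sphere_signal(b, sphere: SphereParams, timing: Timing):
    """Isotropic restricted-sphere attenuation exp(-b D_eff); independent of
    b-tensor shape and direction.  Equals 1 at all b for the dot."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be nonnegative")
    d_eff = sphere_effective_diffusivity(sphere, timing)
    out = np.exp(-b * d_eff)
    return float(out) if out.ndim == 0 else out


def radius_weighted_average(signal_by_radius, histogram: RadiusHistogram):
    """Average a per-radius signal over the histogram with r^2 weights.

    S = sum_i w_i S(eta r_i) / sum_i w_i,  w_i = counts_i * r_i^2.
    With eta = 0 every effective radius is 0, i.e. the stick signal.
    """
    w = histogram.counts * histogram.radii**2
    if w.sum() <= 0:
        raise ValueError("all r^2-weighted counts are zero (all radii zero?)")
    sig = np.array([signal_by_radius(r) for r in histogram.effective_radii])
    return np.tensordot(w, sig, axes=(0, 0)) / w.sum()


def default_radius_histogram(eta: float = 1.0, n_bins: int = 10) -> RadiusHistogram:
    """Synthetic stand-in axon-radius histogram.

    Lognormal with median 0.6 um and sigma_log 0.45, discretized into
    ``n_bins`` equal-probability-range bins; a generic small-axon white
    matter distribution, fully overridable via two-column TSV.
    """
    dist = lognorm(s=0.45, scale=0.6)
    edges = dist.ppf(np.linspace(0.005, 0.995, n_bins + 1))
    centres = 0.5 * (edges[:-1] + edges[1:])
    counts = np.diff(dist.cdf(edges))
    return RadiusHistogram(radii=centres, counts=counts, eta=eta)


def read_radius_histogram(path, eta: float = 1.0) -> RadiusHistogram:
    """Read a two-column (radius_um, count) TSV."""
    arr = np.loadtxt(path)
    arr = np.atleast_2d(arr)
    return RadiusHistogram(radii=arr[:, 0], counts=arr[:, 1], eta=eta)
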