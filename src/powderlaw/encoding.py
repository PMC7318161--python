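"""Axisymmetric b-tensors, gradient direction sets, rotations, and protocols.

Diffusion weighting is carried internally in ms/um^2 so that b*D is
dimensionless when diffusivities are in um^2/ms.  All file I/O (FSL-style
.bval) uses s/mm^2; the conversion factor is exactly 1000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "S_MM2_PER_MS_UM2",
    "AxisymmetricBTensor",
    "DirectionSet",
    "Timing",
    "Protocol",
    "make_btensor",
    "generate_directions",
    "generate_rotations",
    "build_protocol",
    "sphere_quadrature",
    "write_scheme",
    "read_scheme",
]

#: 1 ms/um^2 expressed in s/mm^2.
S_MM2_PER_MS_UM2 = 1000.0

#: Allowed range of the b-tensor shape parameter (eigenvalue nonnegativity).
BDELTA_MIN, BDELTA_MAX = -0.5, 1.0

#: Shape parameters of the three named encodings.
BDELTA_LTE, BDELTA_PTE, BDELTA_STE = 1.0, -0.5, 0.0


def _check_bdelta(b_delta: float) -> None:
    if not (BDELTA_MIN - 1e-12 <= b_delta <= BDELTA_MAX + 1e-12):
        raise ValueError(
            f"b_delta={b_delta} outside [{BDELTA_MIN}, {BDELTA_MAX}] "
            "(b-tensor eigenvalues would be negative)"
        )


def make_btensor(b: float, b_delta: float, g) -> np.ndarray:
    """Expand (b, b_delta, g) into the 3x3 b-matrix.

    B = b/3 (1 - b_delta) I + b b_delta g g^T.  b in ms/um^2 (any unit is
    fine; B inherits it).  g is the symmetry axis; the tensor is invariant
    under g -> -g.
    """
    if b < 0:
        raise ValueError("b must be nonnegative")
    _check_bdelta(b_delta)
    g = np.asarray(g, dtype=float)
    nrm = np.linalg.norm(g)
    if abs(nrm - 1.0) > 1e-6:
        raise ValueError(f"g must be a unit vector (|g| = {nrm:.3g})")
    if abs(nrm - 1.0) > 1e-12:
        warnings.warn("normalizing g (|g| - 1 within 1e-6)", stacklevel=2)
    g = g / nrm
    return b / 3.0 * (1.0 - b_delta) * np.eye(3) + b * b_delta * np.outer(g, g)


@dataclass(frozen=True)
class AxisymmetricBTensor:
    """One diffusion-encoding unit: b-value, shape b_delta, symmetry axis g.

    Eigenvalues are b_par = b(1+2 b_delta)/3 along g (multiplicity 1) and
    b_perp = b(1-b_delta)/3 (multiplicity 2); b_delta =
    (b_par - b_perp)/(b_par + 2 b_perp) recovers the shape.
    """

    b: float
    b_delta: float
    g: np.ndarray

    def __post_init__(self):
        if self.b < 0:
            raise ValueError("b must be nonnegative")
        _check_bdelta(self.b_delta)
        g = np.asarray(self.g, dtype=float)
        nrm = np.linalg.norm(g)
        if abs(nrm - 1.0) > 1e-6:
            raise ValueError("g must be a unit vector")
        object.__setattr__(self, "g", g / nrm)

    @property
    def matrix(self) -> np.ndarray:
        return make_btensor(self.b, self.b_delta, self.g)

    @property
    def b_par(self) -> float:
        return self.b * (1.0 + 2.0 * self.b_delta) / 3.0

    @property
    def b_perp(self) -> float:
        return self.b * (1.0 - self.b_delta) / 3.0

    @classmethod
    def from_eigenvalues(cls, b_par: float, b_perp: float, g) -> "AxisymmetricBTensor":
        b = b_par + 2.0 * b_perp
        b_delta = 0.0 if b == 0 else (b_par - b_perp) / b
        return cls(b=b, b_delta=b_delta, g=g)


# ---------------------------------------------------------------------------
# Direction sets: antipodal electrostatic repulsion on the unit sphere
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DirectionSet:
    """n unit vectors treated as antipodally symmetric encoding axes."""

    vectors: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        nrm = np.linalg.norm(v, axis=1)
        if np.any(np.abs(nrm - 1.0) > 1e-10):
            v = v / nrm[:, None]
        object.__setattr__(self, "vectors", v)

    @property
    def n_dirs(self) -> int:
        return self.vectors.shape[0]

    def min_angle_deg(self) -> float:
        """Smallest pairwise angle, folding antipodes (axes, not vectors)."""
        if self.n_dirs < 2:
            return 180.0
        c = np.abs(self.vectors @ self.vectors.T)
        np.fill_diagonal(c, 0.0)
        return float(np.degrees(np.arccos(np.clip(c.max(), -1, 1))))


def _antipodal_energy_grad(x: np.ndarray, n: int):
    """Coulomb-like energy sum 1/sin^2(theta_ij) over axis pairs, with gradient.

    x is the flattened (n, 3) array of (not necessarily unit) points; the
    energy is evaluated on the normalized points, which keeps the optimizer
    unconstrained.
    """
    p = x.reshape(n, 3)
    nrm = np.linalg.norm(p, axis=1, keepdims=True)
    u = p / nrm
    c = u @ u.T
    c2 = c * c
    np.fill_diagonal(c2, 0.0)
    s2 = 1.0 - c2
    s2 = np.maximum(s2, 1e-12)
    inv = 1.0 / s2
    np.fill_diagonal(inv, 0.0)
    energy = 0.5 * float(inv.sum())  # each pair once
    # dE/dc_ij = 2 c_ij / s2_ij^2 ; dc_ij/du_i = u_j
    w = 2.0 * c * inv * inv
    np.fill_diagonal(w, 0.0)
    g_u = w @ u  # (n, 3)
    # project through normalization: du/dp = (I - u u^T)/|p|
    g_p = (g_u - (np.sum(g_u * u, axis=1, keepdims=True)) * u) / nrm
    return energy, g_p.ravel()


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Fibonacci lattice mapped to the upper hemisphere (antipodal use)."""
    i = np.arange(n) + 0.5
    z = i / n  # (0, 1): hemisphere
    phi = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def generate_directions(
    n: int,
    seed: int | None = 0,
    n_restarts: int = 10,
    method: str = "repulsion",
) -> DirectionSet:
    """Build n approximately uniform encoding axes on the half sphere.

    ``repulsion`` (default) minimizes the antipodal Coulomb energy
    sum_{i<j} 1/sin^2(theta_ij) from ``n_restarts`` seeded random starts and
    keeps the best; deterministic for fixed (n, seed, n_restarts).
    ``fibonacci`` is a fast deterministic fallback.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return DirectionSet(np.array([[0.0, 0.0, 1.0]]), seed=seed)
    if method == "fibonacci":
        return DirectionSet(_fibonacci_hemisphere(n), seed=seed)
    if method != "repulsion":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    best, best_e = None, np.inf
    for _ in range(max(1, n_restarts)):
        x0 = rng.standard_normal((n, 3))
        x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
        res = minimize(
            _antipodal_energy_grad,
            x0.ravel(),
            args=(n,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "gtol": 1e-10},
        )
        if res.fun < best_e:
            best_e, best = res.fun, res.x.reshape(n, 3)
    best = best / np.linalg.norm(best, axis=1, keepdims=True)
    # canonical hemisphere + deterministic ordering for reproducibility
    flip = best[:, 2] < 0
    best[flip] *= -1.0
    order = np.lexsort((best[:, 1], best[:, 0], -best[:, 2]))
    return DirectionSet(best[order], seed=seed)


def generate_rotations(m: int, seed: int | None = 0, n_restarts: int = 10) -> np.ndarray:
    """m rotation matrices whose z-axis images cover the sphere uniformly.

    The principal-axis images come from an antipodal repulsion set (both
    hemispheres used alternately); the roll angle about the axis is a
    deterministic golden-angle sequence.  Returns an (m, 3, 3) array of
    proper rotations.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    half = (m + 1) // 2
    axes_half = generate_directions(half, seed=seed, n_restarts=n_restarts).vectors
    axes = np.concatenate([axes_half, -axes_half])[:m]
    rolls = np.pi * (3.0 - 5.0**0.5) * np.arange(m)
    out = np.empty((m, 3, 3))
    z = np.array([0.0, 0.0, 1.0])
    for i, (a, roll) in enumerate(zip(axes, rolls)):
        v = np.cross(z, a)
        s, c = np.linalg.norm(v), float(np.dot(z, a))
        if s < 1e-12:
            r_align = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            r_align = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        cr, sr = np.cos(roll), np.sin(roll)
        r_roll = np.array([[cr, -sr, 0], [sr, cr, 0], [0, 0, 1.0]])
        out[i] = r_align @ r_roll
    return out


# ---------------------------------------------------------------------------
# Spherical quadrature (used by the Gaussian/Watson orientation integrals)
# ---------------------------------------------------------------------------


def sphere_quadrature(degree: int = 35):
    """Nodes and weights for integrating over the unit sphere.

    Product rule: Gauss-Legendre in cos(theta) x uniform trapezoid in phi,
    exact for spherical harmonics up to ``degree``.  Weights sum to 4*pi.

    Returns (points (k, 3), weights (k,)).
    """
    n_polar = (degree + 2) // 2
    n_az = degree + 1
    mu, w_mu = np.polynomial.legendre.leggauss(n_polar)
    phi = 2.0 * np.pi * np.arange(n_az) / n_az
    w_phi = 2.0 * np.pi / n_az
    sin_t = np.sqrt(1.0 - mu**2)
    pts = np.empty((n_polar * n_az, 3))
    wts = np.empty(n_polar * n_az)
    k = 0
    for i in range(n_polar):
        pts[k : k + n_az, 0] = sin_t[i] * np.cos(phi)
        pts[k : k + n_az, 1] = sin_t[i] * np.sin(phi)
        pts[k : k + n_az, 2] = mu[i]
        wts[k : k + n_az] = w_mu[i] * w_phi
        k += n_az
    return pts, wts


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Timing:
    """Pulsed-gradient timing for restricted compartments.

    delta: gradient pulse width (ms); Delta: pulse separation (ms);
    D0: intrinsic diffusivity inside the restriction (um^2/ms).
    """

    delta: float = 15.0
    Delta: float = 30.0
    D0: float = 2.0

    def __post_init__(self):
        if not (0 < self.delta <= self.Delta):
            raise ValueError("need 0 < delta <= Delta")
        if self.D0 <= 0:
            raise ValueError("D0 must be positive")


@dataclass(frozen=True)
class Protocol:
    """Multi-shell acquisition: list of (b [ms/um^2], b_delta, DirectionSet).

    b = 0 shells act as the normalization reference; n_b0 counts extra
    interleaved b = 0 volumes beyond any b = 0 shell.
    """

    shells: tuple
    n_b0: int = 0
    timing: Timing = field(default_factory=Timing)

    def __post_init__(self):
        for b, b_delta, _ in self.shells:
            if b < 0:
                raise ValueError("shell b-values must be nonnegative")
            _check_bdelta(b_delta)

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + sum(ds.n_dirs for _, _, ds in self.shells)

    def volume_table(self):
        """Flatten to per-volume arrays (bvals, bdeltas, dirs, shell_idx).

        Interleaved b0 volumes carry shell_idx = -1 and direction e_z.
        bvals in ms/um^2.
        """
        bs, bds, gs, idx = [], [], [], []
        for _ in range(self.n_b0):
            bs.append(0.0)
            bds.append(0.0)
            gs.append([0.0, 0.0, 1.0])
            idx.append(-1)
        for i, (b, bd, ds) in enumerate(self.shells):
            for g in ds.vectors:
                bs.append(b)
                bds.append(bd)
                gs.append(g)
                idx.append(i)
        return (
            np.array(bs),
            np.array(bds),
            np.array(gs, dtype=float),
            np.array(idx),
        )

    def shell_bvals(self) -> np.ndarray:
        return np.array([b for b, _, _ in self.shells])


def build_protocol(
    spec,
    b_delta: float = 1.0,
    n_dirs: int = 60,
    seed: int = 0,
    timing: Timing | None = None,
    direction_method: str = "repulsion",
) -> Protocol:
    """Build a named preset or an explicit shell list.

    ``"sim21"``: 21 b-values 0..10 s/mm^2 x1000 step 0.5 (i.e. 0..10000
    s/mm^2 step 500), 60 directions each.  ``"invivo10"``: 10 shells
    1000..10000 s/mm^2 step 1000, 60 directions, 11 interleaved b0 volumes.
    Explicit: an iterable of (b_s_mm2, b_delta) pairs.
    """
    timing = timing or Timing()
    dirs = generate_directions(n_dirs, seed=seed, method=direction_method)
    if isinstance(spec, str):
        if spec == "sim21":
            bvals = np.arange(0.0, 10000.1, 500.0)
            shells = tuple((b / S_MM2_PER_MS_UM2, b_delta, dirs) for b in bvals)
            return Protocol(shells=shells, n_b0=0, timing=timing)
        if spec == "invivo10":
            bvals = np.arange(1000.0, 10000.1, 1000.0)
            shells = tuple((b / S_MM2_PER_MS_UM2, b_delta, dirs) for b in bvals)
            return Protocol(shells=shells, n_b0=11, timing=timing)
        raise ValueError(f"unknown protocol preset {spec!r}; use 'sim21' or 'invivo10'")
    shells = tuple((b / S_MM2_PER_MS_UM2, bd, dirs) for b, bd in spec)
    return Protocol(shells=shells, n_b0=0, timing=timing)


# ---------------------------------------------------------------------------
# FSL-style sidecar I/O (.bval/.bvec in s/mm^2 + .bdelta, one row each)
# ---------------------------------------------------------------------------


def write_scheme(protocol: Protocol, prefix: str) -> None:
    bvals, bdeltas, gs, _ = protocol.volume_table()
    np.savetxt(prefix + ".bval", (bvals * S_MM2_PER_MS_UM2)[None, :], fmt="%.17g")
    np.savetxt(prefix + ".bvec", gs.T, fmt="%.17g")
    np.savetxt(prefix + ".bdelta", bdeltas[None, :], fmt="%.17g")


def read_scheme(prefix: str):
    """Read .bval/.bvec/.bdelta sidecars -> (bvals ms/um^2, bdeltas, dirs)."""
    import os

    for ext in (".bval", ".bvec", ".bdelta"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(f"missing sidecar file: {prefix + ext}")
    bvals = np.atleast_1d(np.loadtxt(prefix + ".bval")) / S_MM2_PER_MS_UM2
    gs = np.atleast_2d(np.loadtxt(prefix + ".bvec")).T
    bdeltas = np.atleast_1d(np.loadtxt(prefix + ".bdelta"))
    if not (len(bvals) == gs.shape[0] == len(bdeltas)):
        raise ValueError(
            f"sidecar length mismatch: {len(bvals)} bvals, "
            f"{gs.shape[0]} bvecs, {len(bdeltas)} bdeltas"
        )
    return bvals, bdeltas, gs
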