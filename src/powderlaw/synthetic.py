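"""Synthetic multi-shell DWI: three-compartment Watson tissue + Rician noise.

The noise-free voxel signal is

    S/S0 = f1 * int W(n) S_cyl(n) dn + f2 * int W(n) S_ec(n) dn + f3 * S_sph

with W a Watson orientation distribution of concentration kappa about a mean
axis mu, S_cyl the radius-averaged impermeable-cylinder attenuation
(intra-axonal), S_ec an axially symmetric Gaussian (extra-axonal) and S_sph
an isotropic restricted sphere (R_s = 8 um) or dot (R_s = 0).  Orientation
integrals use a spherical product quadrature whose degree escalates with
kappa.  Magnitude noise is Rician: sqrt((S + N_r)^2 + N_i^2) with N_r, N_i
zero-mean Gaussians of standard deviation sigma; in b0-normalized units
sigma = 1 / SNR_b0 (the study condition is SNR_b0 = 150).

Default tissue: f1 = 0.65, f2 = 0.35, f3 = 0, D_a_par = D_e_par = 2 um^2/ms,
D_e_perp = 0.5 um^2/ms, kappa = 11.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import hyp1f1

from .encoding import (
    S_MM2_PER_MS_UM2,
    Protocol,
    Timing,
    read_scheme,
    sphere_quadrature,
    write_scheme,
)
from .restricted import (
    RadiusHistogram,
    SphereParams,
    cylinder_perp_diffusivity,
    default_radius_histogram,
    sphere_signal,
)

__all__ = [
    "TissueModel",
    "DWIDataset",
    "watson_density",
    "watson_quadrature_degree",
    "simulate_voxel",
    "add_rician_noise",
    "tissue_presets",
    "make_phantom_volume",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class TissueModel:
    """Three-compartment Watson-dispersed tissue (fractions sum to 1)."""

    f1: float = 0.65
    f2: float = 0.35
    f3: float = 0.0
    D_a_par: float = 2.0
    D_e_par: float = 2.0
    D_e_perp: float = 0.5
    kappa: float = 11.0
    mu: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    radius_hist: RadiusHistogram | None = None
    sphere: SphereParams = field(default_factory=lambda: SphereParams(R_s=0.0))

    def __post_init__(self):
        for f in (self.f1, self.f2, self.f3):
            if f < -1e-12:
                raise ValueError("signal fractions must be nonnegative")
        if abs(self.f1 + self.f2 + self.f3 - 1.0) > 1e-9:
            raise ValueError("signal fractions must sum to 1")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu / np.linalg.norm(mu))
        if self.radius_hist is None:
            object.__setattr__(self, "radius_hist", default_radius_histogram(eta=0.0))

    def with_third_fraction(self, f3: float, sphere: SphereParams | None = None) -> "TissueModel":
        """Set the dot/sphere fraction, shrinking f1 and f2 proportionally."""
        if not (0 <= f3 < 1):
            raise ValueError("f3 must lie in [0, 1)")
        scale = (1.0 - f3) / (self.f1 + self.f2)
        return replace(
            self,
            f1=self.f1 * scale,
            f2=self.f2 * scale,
            f3=f3,
            sphere=sphere if sphere is not None else self.sphere,
        )


def watson_density(n, mu, kappa: float):
    """Watson ODF: exp(kappa (mu.n)^2) / (4 pi M(1/2, 3/2, kappa)).

    Antipodally symmetric; kappa = 0 is uniform (1/4pi); integrates to 1
    over the sphere.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    c2 = (n @ mu) ** 2
    # Kummer transform M(1/2,3/2,k) = e^k M(1,3/2,-k) keeps this finite at
    # arbitrarily large concentration.
    return np.exp(kappa * (c2 - 1.0)) / (4.0 * np.pi * hyp1f1(1.0, 1.5, -kappa))


def watson_quadrature_degree(kappa: float, base: int = 35) -> int:
    """Quadrature degree that resolves a Watson density of concentration
    kappa (nodes must sample the O(1/kappa) polar caps)."""
    return max(base, int(np.ceil(9.0 * np.sqrt(max(kappa, 1.0)))) + base)


def _shape_coeffs(bvals, bdeltas, d_par, d_perp):
    """Per-volume (A, C) with tr(B D(n)) = A + C (g.n)^2 for an axially
    symmetric compartment of diffusivities (d_par, d_perp)."""
    diff = d_par - d_perp
    A = bvals * d_perp + diff * bvals * (1.0 - bdeltas) / 3.0
    C = diff * bvals * bdeltas
    return A, C


def simulate_voxel(
    tissue: TissueModel,
    protocol: Protocol,
    quad_degree: int | None = None,
) -> np.ndarray:
    """Noise-free b0-normalized signal for every volume of the protocol.

    Orientation integrals run on a spherical quadrature of degree
    ``quad_degree`` (defaults to a kappa-dependent escalation of 35); an
    explicit degree too low for the requested kappa raises.
    """
    auto = watson_quadrature_degree(tissue.kappa)
    if quad_degree is None:
        quad_degree = auto
    elif tissue.kappa > 50 and quad_degree < auto:
        raise ValueError(
            f"quadrature degree {quad_degree} too low for kappa={tissue.kappa}; "
            f"use >= {auto}"
        )
    bvals, bdeltas, gs, _ = protocol.volume_table()
    pts, wts = sphere_quadrature(quad_degree)
    w_watson = wts * watson_density(pts, tissue.mu, tissue.kappa)  # sums to ~1
    dot2 = (gs @ pts.T) ** 2  # (n_vol, n_quad)

    signal = np.zeros(len(bvals))
    timing = protocol.timing
    if tissue.f1 > 0:
        hist = tissue.radius_hist
        w_r = hist.counts * hist.radii**2
        if w_r.sum() <= 0:  # degenerate all-zero-radius histogram: pure stick
            w_r = hist.counts
        w_r = w_r / w_r.sum()
        intra = np.zeros(len(bvals))
        for wr, r_eff in zip(w_r, hist.effective_radii):
            d_perp = cylinder_perp_diffusivity(
                r_eff, D0=timing.D0, delta=timing.delta, Delta=timing.Delta
            )
            A, C = _shape_coeffs(bvals, bdeltas, tissue.D_a_par, d_perp)
            intra += wr * (np.exp(-A[:, None] - C[:, None] * dot2) @ w_watson)
        signal += tissue.f1 * intra
    if tissue.f2 > 0:
        A, C = _shape_coeffs(bvals, bdeltas, tissue.D_e_par, tissue.D_e_perp)
        signal += tissue.f2 * (np.exp(-A[:, None] - C[:, None] * dot2) @ w_watson)
    if tissue.f3 > 0:
        signal += tissue.f3 * sphere_signal(bvals, tissue.sphere, timing)
    signal[bvals == 0] = (tissue.f1 + tissue.f2 + tissue.f3)  # exact S(0) = 1
    return signal


def add_rician_noise(signals, sigma: float, seed: int | None = 0) -> np.ndarray:
    """Magnitude (Rician) noise: sqrt((S+N_r)^2 + N_i^2), N ~ Normal(0, sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    signals = np.asarray(signals, dtype=float)
    if sigma == 0:
        return signals.copy()
    rng = np.random.default_rng(seed)
    n_r = rng.normal(0.0, sigma, signals.shape)
    n_i = rng.normal(0.0, sigma, signals.shape)
    return np.sqrt((signals + n_r) ** 2 + n_i**2)


@dataclass(frozen=True)
class DWIDataset:
    """Signals (voxel grid x volumes, b0-normalized units) + acquisition."""

    protocol: Protocol
    signals: np.ndarray
    sigma: float = 0.0
    seed: int | None = None
    labels: np.ndarray | None = None

    def __post_init__(self):
        s = np.asarray(self.signals)
        if s.shape[-1] != self.protocol.n_volumes:
            raise ValueError(
                f"last signal axis ({s.shape[-1]}) must match protocol volume "
                f"count ({self.protocol.n_volumes})"
            )
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValueError("signals must be finite and nonnegative")
        object.__setattr__(self, "signals", s)


def tissue_presets() -> dict:
    """WM/GM/CSF-like presets for phantom volumes.

    WM: the default two-compartment Watson tissue.  GM: stick + restricted
    sphere (R_s = 8 um) mixture with lower anisotropic fraction.  CSF: free
    water, an isotropic Gaussian with D = 3 um^2/ms.
    """
    wm = TissueModel()
    gm = TissueModel(f1=0.45, f2=0.25, f3=0.30, kappa=2.0, sphere=SphereParams(R_s=8.0))
    csf = TissueModel(f1=0.0, f2=1.0, f3=0.0, D_e_par=3.0, D_e_perp=3.0, kappa=0.0)
    return {"WM": wm, "GM": gm, "CSF": csf}


def make_phantom_volume(
    layout: np.ndarray,
    presets: dict,
    protocol: Protocol,
    snr_b0: float = 150.0,
    seed: int | None = 0,
) -> DWIDataset:
    """Build a labelled 4-D phantom with Rician noise (sigma = 1/snr_b0).

    ``layout`` is a 3-D array of label strings; voxels labelled
    ``"background"`` (or ``""``) hold zero signal plus pure noise, so the
    Rayleigh-background noise estimator can be exercised.  Voxels sharing a
    label share the same noise-free signal; noise is voxel-independent.
    """
    layout = np.asarray(layout)
    if layout.size == 0:
        raise ValueError("layout must contain at least one voxel")
    if snr_b0 <= 0:
        raise ValueError("snr_b0 must be positive")
    sigma = 1.0 / snr_b0
    n_vol = protocol.n_volumes
    clean = np.zeros(layout.shape + (n_vol,))
    for lab in np.unique(layout):
        if lab in ("background", ""):
            continue
        if lab not in presets:
            raise KeyError(f"layout label {lab!r} has no tissue preset")
        clean[layout == lab] = simulate_voxel(presets[lab], protocol)
    noisy = add_rician_noise(clean, sigma, seed=seed)
    return DWIDataset(protocol=protocol, signals=noisy, sigma=sigma, seed=seed, labels=layout)


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O
# ---------------------------------------------------------------------------


def _strip_nii(path: str) -> str:
    for ext in (".nii.gz", ".nii"):
        if path.endswith(ext):
            return path[: -len(ext)]
    return path


def write_dataset(dataset: DWIDataset, path: str) -> None:
    """Write 4-D NIfTI (float32) + .bval/.bvec/.bdelta + JSON sidecar."""
    import nibabel as nib

    prefix = _strip_nii(path)
    if not (path.endswith(".nii") or path.endswith(".nii.gz")):
        path = prefix + ".nii.gz"
    sig = np.asarray(dataset.signals, dtype=np.float32)
    if sig.ndim == 1:
        sig = sig.reshape(1, 1, 1, -1)
    while sig.ndim < 4:
        sig = sig[None]
    nib.save(nib.Nifti1Image(sig, np.eye(4)), path)
    write_scheme(dataset.protocol, prefix)
    t = dataset.protocol.timing
    meta = {
        "sigma": dataset.sigma,
        "seed": dataset.seed,
        "n_b0": dataset.protocol.n_b0,
        "timing_ms": {"delta": t.delta, "Delta": t.Delta},
        "D0_um2_ms": t.D0,
        "b_units": "s/mm^2 in .bval; internal ms/um^2",
    }
    with open(prefix + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_dataset(path: str) -> DWIDataset:
    """Read a dataset written by :func:`write_dataset` (protocol exact,
    signals as stored float32)."""
    import nibabel as nib

    from .encoding import DirectionSet

    prefix = _strip_nii(path)
    if not os.path.exists(path):
        for ext in (".nii.gz", ".nii"):
            if os.path.exists(prefix + ext):
                path = prefix + ext
                break
    sig = np.asarray(nib.load(path).dataobj, dtype=np.float32)
    bvals, bdeltas, gs = read_scheme(prefix)
    meta = {}
    if os.path.exists(prefix + ".json"):
        with open(prefix + ".json") as fh:
            meta = json.load(fh)
    n_b0 = int(meta.get("n_b0", 0))
    tm = meta.get("timing_ms", {})
    timing = Timing(
        delta=tm.get("delta", 15.0), Delta=tm.get("Delta", 30.0), D0=meta.get("D0_um2_ms", 2.0)
    )
    # regroup post-b0 volumes into consecutive-(b, b_delta) shells
    shells = []
    i = n_b0
    while i < len(bvals):
        j = i
        while (
            j < len(bvals) and bvals[j] == bvals[i] and bdeltas[j] == bdeltas[i]
        ):
            j += 1
        shells.append((float(bvals[i]), float(bdeltas[i]), DirectionSet(gs[i:j])))
        i = j
    protocol = Protocol(shells=tuple(shells), n_b0=n_b0, timing=timing)
    return DWIDataset(
        protocol=protocol,
        signals=sig,
        sigma=float(meta.get("sigma", 0.0)),
        seed=meta.get("seed"),
    )
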