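"""Powder averaging, power-law fitting, noise floors, and direction counts.

The direction-averaged (powder) signal at high b is summarized by a
two-parameter power law S = beta * b^(-alpha) (b in ms/um^2), fitted by
bounded trust-region least squares in linear signal space from the fixed
start (alpha, beta) = (1, 0.2); goodness of fit by BIC.  Theory predicts
alpha = 1/2 for linear-encoded sticks and alpha = 1 for planar-encoded
sticks, with beta -> f / D_a_par for the planar case.

The rectified-noise-floor analysis asks how far b*D can be pushed before the
powder average reaches twice the Rayleigh background mean, i.e. solves
S_shape(bD) = 2 sqrt(pi/2) / SNR_b0 per encoding shape.  The
rotational-invariance analysis reproduces the minimum-direction-count
criterion: simulate S = exp(-tr(B D)) for an axisymmetric tensor (MD, FA)
under many tensor orientations and find the smallest direction count whose
per-shell powder average has CV = SD/mean below threshold at every shell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .encoding import BDELTA_LTE, BDELTA_PTE, BDELTA_STE, generate_directions, generate_rotations
from .gaussian import pte_stick_signal
from .synthetic import DWIDataset, TissueModel, add_rician_noise, simulate_voxel

__all__ = [
    "PowerLawFit",
    "SNREstimate",
    "powder_average",
    "fit_powerlaw",
    "estimate_sigma_snr",
    "max_bD_noise_floor",
    "min_directions_for_invariance",
    "sweep_fraction",
    "alpha_map",
    "NOISE_FLOOR_FACTOR",
    "axisymmetric_tensor_from_md_fa",
]

#: Rayleigh mean is sigma*sqrt(pi/2); the floor criterion is signal = twice
#: the background mean, i.e. S * SNR_b0 = 2*sqrt(pi/2).
NOISE_FLOOR_FACTOR = 2.0 * np.sqrt(np.pi / 2.0)

#: default fit window, ms/um^2 (7000-10000 s/mm^2)
DEFAULT_B_RANGE = (7.0, 10.0)


@dataclass(frozen=True)
class PowerLawFit:
    """Result of fitting S = beta * b^(-alpha) over a b window."""

    alpha: float
    beta: float
    rss: float
    bic: float
    n_points: int
    converged: bool


@dataclass(frozen=True)
class SNREstimate:
    """Noise SD from a Rayleigh background and foreground-referenced SNR."""

    sigma_hat: float
    snr: float


def powder_average(dataset: DWIDataset):
    """Per-voxel, per-shell direction average, b0-normalized.

    Returns (shell_b, shell_bdelta, curves): shells sorted by b (b = 0
    shells excluded from the curve; they join the interleaved b0 volumes as
    the normalization reference).  Voxels whose mean b0 is nonpositive are
    returned as NaN curves.
    """
    bvals, bdeltas, _, shell_idx = dataset.protocol.volume_table()
    sig = np.asarray(dataset.signals, dtype=float)
    flat = sig.reshape(-1, sig.shape[-1])
    b0_cols = bvals == 0
    if not np.any(b0_cols):
        raise ValueError("dataset has no b = 0 volumes to normalize against")
    b0 = flat[:, b0_cols].mean(axis=1)
    bad = b0 <= 0
    shells = [
        (b, bd, i)
        for i, (b, bd, _) in enumerate(dataset.protocol.shells)
        if b > 0
    ]
    shells.sort(key=lambda t: t[0])
    curves = np.empty((flat.shape[0], len(shells)))
    for j, (_, _, i) in enumerate(shells):
        curves[:, j] = flat[:, shell_idx == i].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        curves /= b0[:, None]
    curves[bad] = np.nan
    shell_b = np.array([b for b, _, _ in shells])
    shell_bd = np.array([bd for _, bd, _ in shells])
    curves = curves.reshape(sig.shape[:-1] + (len(shells),))
    return shell_b, shell_bd, curves


def fit_powerlaw(
    b,
    signal,
    b_range: tuple = DEFAULT_B_RANGE,
    x0: tuple = (1.0, 0.2),
    bounds: tuple = ((0.0, 0.0), (5.0, 10.0)),
) -> PowerLawFit:
    """Trust-region least-squares fit of S = beta * b^(-alpha), b in ms/um^2.

    Only shells with b inside ``b_range`` (inclusive) enter the fit; the fit
    runs in linear signal space.  BIC = n ln(rss/n) + p ln(n) with p = 2.
    ``converged`` is False if the optimizer failed or a parameter sits on a
    bound (degenerate curves).
    """
    b = np.asarray(b, dtype=float)
    signal = np.asarray(signal, dtype=float)
    sel = (b >= b_range[0] - 1e-12) & (b <= b_range[1] + 1e-12)
    bb, ss = b[sel], signal[sel]
    if len(bb) < 2:
        raise ValueError(f"need >= 2 shells inside b_range {b_range}, got {len(bb)}")
    if np.any(~np.isfinite(ss)) or np.any(ss <= 0):
        raise ValueError("signals in the fit window must be positive and finite")

    def resid(p):
        alpha, beta = p
        return beta * bb ** (-alpha) - ss

    res = least_squares(
        resid, x0=np.asarray(x0, float), bounds=bounds, method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    rss = float(np.sum(res.fun**2))
    n = len(bb)
    bic = n * np.log(max(rss / n, 1e-300)) + 2.0 * np.log(n)
    lo, hi = np.asarray(bounds[0]), np.asarray(bounds[1])
    at_bound = bool(np.any(np.abs(res.x - lo) < 1e-4) or np.any(np.abs(res.x - hi) < 1e-4))
    return PowerLawFit(
        alpha=float(res.x[0]),
        beta=float(res.x[1]),
        rss=rss,
        bic=float(bic),
        n_points=n,
        converged=bool(res.success) and not at_bound,
    )


def estimate_sigma_snr(volume, foreground_mask, background_mask) -> SNREstimate:
    """sigma from the Rayleigh background mean; SNR = <foreground>/sigma.

    The background mean of pure-noise magnitudes is sigma*sqrt(pi/2), so
    sigma_hat = sqrt(2/pi) * <M_background>.
    """
    volume = np.asarray(volume, dtype=float)
    fg = volume[np.asarray(foreground_mask, bool)]
    bg = volume[np.asarray(background_mask, bool)]
    if fg.size == 0 or bg.size == 0:
        raise ValueError("foreground and background masks must be nonempty")
    sigma_hat = float(np.sqrt(2.0 / np.pi) * bg.mean())
    return SNREstimate(sigma_hat=sigma_hat, snr=float(fg.mean() / sigma_hat))


def _stick_shape_signal(b_delta: float):
    if b_delta == BDELTA_LTE:
        from scipy.special import erf

        return lambda bD: float(
            np.sqrt(np.pi) * erf(np.sqrt(bD)) / (2.0 * np.sqrt(bD))
        )
    if b_delta == BDELTA_PTE:
        return lambda bD: float(pte_stick_signal(bD))
    if b_delta == BDELTA_STE:
        return lambda bD: float(np.exp(-bD / 3.0))
    raise ValueError("noise-floor analysis supports b_delta in {1, -0.5, 0}")


def max_bD_noise_floor(b_delta: float, snr: float, tol: float = 1e-6) -> float:
    """Largest dimensionless b*D before the powder-averaged stick signal
    falls to twice the Rayleigh background mean (2*sqrt(pi/2)/SNR)."""
    floor = NOISE_FLOOR_FACTOR / snr
    if floor >= 1.0:
        raise ValueError(
            f"SNR {snr} is at or below the floor factor {NOISE_FLOOR_FACTOR:.4f}; "
            "signal never exceeds the noise floor"
        )
    f = _stick_shape_signal(b_delta)
    lo, hi = 1e-9, 10.0
    while f(hi) > floor:
        hi *= 4.0
        if hi > 1e12:
            raise RuntimeError("signal never reaches the noise floor")
    return float(brentq(lambda x: f(x) - floor, lo, hi, xtol=tol))


def axisymmetric_tensor_from_md_fa(MD: float, FA: float) -> tuple[float, float]:
    """(D_par, D_perp) of a prolate axisymmetric tensor with the given mean
    diffusivity and fractional anisotropy."""
    if MD <= 0 or not (0 <= FA < 1):
        raise ValueError("need MD > 0 and 0 <= FA < 1")
    if FA == 0:
        return MD, MD

    def f(d_perp):
        d_par = 3.0 * MD - 2.0 * d_perp
        return (d_par - d_perp) - FA * np.sqrt(d_par**2 + 2.0 * d_perp**2)

    d_perp = brentq(f, 0.0, MD)
    return 3.0 * MD - 2.0 * d_perp, d_perp


def _cv_across_rotations(dirs, axes, b_list, b_delta, d_par, d_perp) -> np.ndarray:
    """CV = SD/mean of the powder average across tensor orientations, per b."""
    dot2 = (dirs @ axes.T) ** 2  # (n_dirs, n_rot)
    diff = d_par - d_perp
    out = np.empty(len(b_list))
    for i, b in enumerate(b_list):
        a = b * d_perp + diff * b * (1.0 - b_delta) / 3.0
        c = diff * b * b_delta
        s = np.exp(-a - c * dot2).mean(axis=0)  # powder average per rotation
        out[i] = s.std() / s.mean()
    return out


def min_directions_for_invariance(
    b_delta: float,
    b_list=(7.0, 8.0, 9.0, 10.0),
    MD: float = 1.0,
    FA: float = 0.95,
    cv_threshold: float = 0.01,
    n_rotations: int = 512,
    seed: int = 0,
    n_max: int = 200,
    return_profile: bool = False,
):
    """Smallest direction count giving a rotationally invariant powder average.

    Gaussian tensor signal S = exp(-tr(B D)); the tensor axis is rotated
    over ``n_rotations`` uniformly distributed orientations and the
    direction count is increased until CV < ``cv_threshold`` at every b in
    ``b_list`` (ms/um^2).  Returns the count (or (count, profile DataFrame)
    with per-candidate CVs if ``return_profile``).
    """
    d_par, d_perp = axisymmetric_tensor_from_md_fa(MD, FA)
    axes = generate_rotations(n_rotations, seed=seed)[:, :, 2]  # z-axis images
    b_list = np.asarray(b_list, dtype=float)
    rows = []
    found = None
    for n in range(1, n_max + 1):
        dirs = generate_directions(n, seed=seed).vectors
        cv = _cv_across_rotations(dirs, axes, b_list, b_delta, d_par, d_perp)
        rows.append([n, *cv])
        if np.all(cv < cv_threshold):
            found = n
            break
    profile = pd.DataFrame(rows, columns=["n_dirs", *[f"cv_b{b:g}" for b in b_list]])
    if found is None:
        found = -1  # no count up to n_max qualified
    return (found, profile) if return_profile else found


def sweep_fraction(
    component: str,
    f3_grid,
    b_delta_list=(BDELTA_LTE, BDELTA_PTE),
    tissue_base: TissueModel | None = None,
    protocol_builder=None,
    snr: float = 150.0,
    n_repeats: int = 20,
    seed: int = 0,
    b_range: tuple = DEFAULT_B_RANGE,
) -> pd.DataFrame:
    """Fitted power-law exponent vs dot/sphere signal fraction.

    ``component`` is ``"dot"`` (R_s = 0) or ``"sphere"`` (R_s = 8 um).  For
    each shape and f3 the three-compartment voxel is simulated on the
    21-shell protocol, Rician noise at the given b0-SNR is added
    ``n_repeats`` times, and the powder average is fitted over ``b_range``;
    mean and SD of (alpha, beta) across repeats are tabulated.
    """
    from .encoding import build_protocol
    from .restricted import SphereParams

    if component not in ("dot", "sphere"):
        raise ValueError("component must be 'dot' or 'sphere'")
    sphere = SphereParams(R_s=0.0 if component == "dot" else 8.0)
    if tissue_base is None:
        from .restricted import default_radius_histogram

        tissue_base = TissueModel(
            D_e_perp=0.75, radius_hist=default_radius_histogram(eta=1.5)
        )
    rows = []
    rng = np.random.default_rng(seed)
    for b_delta in b_delta_list:
        if protocol_builder is None:
            protocol = build_protocol("sim21", b_delta=b_delta, seed=seed)
        else:
            protocol = protocol_builder(b_delta)
        for f3 in np.asarray(f3_grid, dtype=float):
            tissue = tissue_base.with_third_fraction(float(f3), sphere=sphere)
            clean = simulate_voxel(tissue, protocol)
            alphas, betas = [], []
            for _ in range(n_repeats):
                noisy = add_rician_noise(clean, 1.0 / snr, seed=int(rng.integers(2**31)))
                ds = DWIDataset(protocol=protocol, signals=noisy.reshape(1, -1))
                shell_b, _, curves = powder_average(ds)
                fit = fit_powerlaw(shell_b, curves[0], b_range=b_range)
                alphas.append(fit.alpha)
                betas.append(fit.beta)
            rows.append(
                {
                    "component": component,
                    "b_delta": b_delta,
                    "f3": f3,
                    "alpha_mean": float(np.mean(alphas)),
                    "alpha_sd": float(np.std(alphas, ddof=1)) if n_repeats > 1 else 0.0,
                    "beta_mean": float(np.mean(betas)),
                    "beta_sd": float(np.std(betas, ddof=1)) if n_repeats > 1 else 0.0,
                    "n_repeats": n_repeats,
                }
            )
    return pd.DataFrame(rows)


def alpha_map(dataset: DWIDataset, b_range: tuple = DEFAULT_B_RANGE):
    """Voxelwise power-law fit: alpha/beta/BIC/converged maps.

    Voxels that cannot be fitted (no b0, nonpositive signal in the window)
    are masked NaN without aborting the map.  Returns a dict of arrays with
    the dataset's spatial shape.
    """
    shell_b, _, curves = powder_average(dataset)
    spatial = curves.shape[:-1]
    flat = curves.reshape(-1, curves.shape[-1])
    out = {
        k: np.full(flat.shape[0], np.nan)
        for k in ("alpha", "beta", "bic")
    }
    conv = np.zeros(flat.shape[0], dtype=bool)
    for i, curve in enumerate(flat):
        if not np.all(np.isfinite(curve)):
            continue
        try:
            fit = fit_powerlaw(shell_b, curve, b_range=b_range)
        except ValueError:
            continue
        out["alpha"][i] = fit.alpha
        out["beta"][i] = fit.beta
        out["bic"][i] = fit.bic
        conv[i] = fit.converged
    maps = {k: v.reshape(spatial) for k, v in out.items()}
    maps["converged"] = conv.reshape(spatial)
    return maps


def alpha_histogram(maps: dict, labels: np.ndarray, bins=30) -> pd.DataFrame:
    """Per-label alpha summary (mean, SD, histogram counts)."""
    rows = []
    for lab in np.unique(labels):
        if lab in ("background", ""):
            continue
        vals = maps["alpha"][labels == lab]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        hist, edges = np.histogram(vals, bins=bins)
        rows.append(
            {
                "label": lab,
                "n": int(vals.size),
                "alpha_mean": float(vals.mean()),
                "alpha_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "hist_counts": hist.tolist(),
                "hist_edges": edges.tolist(),
            }
        )
    return pd.DataFrame(rows)
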