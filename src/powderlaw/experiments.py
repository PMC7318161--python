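"""Figure-style experiment recipes: each writes TSV tables, a PNG figure,
and a JSON manifest into an output directory, deterministically for a given
configuration and seed."""

from __future__ import annotations

import json
import os
import time

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import analysis, encoding, gaussian, synthetic
from .restricted import default_radius_histogram

__all__ = ["EXPERIMENTS", "run_experiment"]


def _write_manifest(outdir, name, params, seed, t0):
    manifest = {
        "experiment": name,
        "seed": seed,
        "parameters": params,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def fig1(outdir: str, seed: int = 0, **kw):
    """Ratio of the truncated PTE expansion to the exact signal, plus the
    minimum-terms table."""
    t0 = time.time()
    bD = np.arange(3.0, 21.0)
    Ns = np.arange(0, 21)
    ratio = pd.DataFrame(
        [[gaussian.pte_asymptotic(b, int(n)).value / gaussian.pte_stick_signal(b) for b in bD] for n in Ns],
        index=Ns,
        columns=bD,
    )
    ratio.to_csv(os.path.join(outdir, "approx_over_exact.tsv"), sep="\t")
    table = gaussian.min_terms_table(bD, [0.06, 0.05, 0.04, 0.03, 0.02, 0.01])
    table.to_csv(os.path.join(outdir, "min_terms.tsv"), sep="\t", na_rep="-")
    fig, ax = plt.subplots(figsize=(6, 4))
    for n in (0, 1, 2, 3, 5, 10):
        ax.plot(bD, ratio.loc[n], label=f"N={n}")
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set(xlabel="b·D_par (dimensionless)", ylabel="approx / exact", ylim=(0, 2))
    ax.legend(fontsize=7)
    fig.savefig(os.path.join(outdir, "fig.png"), dpi=120)
    plt.close(fig)
    _write_manifest(outdir, "fig1", {}, seed, t0)


def fig3(outdir: str, seed: int = 0, snr_grid=None, **kw):
    """Maximum b*D before the rectified-noise floor vs SNR per encoding."""
    t0 = time.time()
    snr_grid = np.asarray(snr_grid if snr_grid is not None else np.arange(5, 201, 5), float)
    rows = []
    for snr in snr_grid:
        row = {"snr": snr}
        for bd, name in [(1.0, "LTE"), (-0.5, "PTE"), (0.0, "STE")]:
            try:
                row[name] = analysis.max_bD_noise_floor(bd, snr)
            except ValueError:
                row[name] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(outdir, "max_bD_vs_snr.tsv"), sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    for name in ("LTE", "PTE", "STE"):
        ax.loglog(df["snr"], df[name], label=name)
    ax.set(xlabel="SNR at b=0", ylabel="max b·D before noise floor")
    ax.legend()
    fig.savefig(os.path.join(outdir, "fig.png"), dpi=120)
    plt.close(fig)
    _write_manifest(outdir, "fig3", {"snr_grid": snr_grid.tolist()}, seed, t0)


def fig4(outdir: str, seed: int = 0, snr: float = 150.0, **kw):
    """Power-law fits to simulated planar-encoded powder averages for three
    perpendicular diffusivities x three shrinkage factors."""
    t0 = time.time()
    d_perps, etas = [0.25, 0.5, 0.75], [0.0, 1.0, 1.5]
    protocol = encoding.build_protocol("sim21", b_delta=-0.5, seed=seed)
    rows = []
    fig, axes_grid = plt.subplots(3, 3, figsize=(10, 9), sharex=True)
    for i, eta in enumerate(etas):
        for j, dp in enumerate(d_perps):
            tissue = synthetic.TissueModel(
                D_e_perp=dp, radius_hist=default_radius_histogram(eta=eta)
            )
            clean = synthetic.simulate_voxel(tissue, protocol)
            noisy = synthetic.add_rician_noise(clean, 1.0 / snr, seed=seed + 13 * i + j)
            ds = synthetic.DWIDataset(protocol=protocol, signals=noisy.reshape(1, -1))
            shell_b, _, curves = analysis.powder_average(ds)
            fit = analysis.fit_powerlaw(shell_b, curves[0])
            rows.append(
                {"eta": eta, "D_e_perp": dp, "alpha": fit.alpha, "beta": fit.beta, "bic": fit.bic}
            )
            ax = axes_grid[i, j]
            sel = (shell_b >= 7.0) & (shell_b <= 10.0)
            ax.plot(1.0 / shell_b[sel], curves[0][sel], "o", ms=3)
            bb = np.linspace(7, 10, 50)
            ax.plot(1.0 / bb, fit.beta * bb**-fit.alpha, "r--", lw=1)
            ax.set_title(f"eta={eta}, De_perp={dp}\nalpha={fit.alpha:.2f} beta={fit.beta:.2f}", fontsize=7)
    fig.supxlabel("1/b (um^2/ms)")
    fig.supylabel("powder-averaged S/S0")
    fig.savefig(os.path.join(outdir, "fig.png"), dpi=120)
    plt.close(fig)
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "fits.tsv"), sep="\t", index=False)
    _write_manifest(outdir, "fig4", {"snr": snr}, seed, t0)


def fig5a(outdir: str, seed: int = 0, n_rotations: int = 512, b_list=None, **kw):
    """Minimum direction count for a rotationally invariant powder average,
    per b-value, for linear and planar encoding."""
    t0 = time.time()
    b_list = list(b_list) if b_list is not None else [float(b) for b in range(1, 11)]
    rows = []
    for bd, name in [(1.0, "LTE"), (-0.5, "PTE")]:
        for b in b_list:
            n = analysis.min_directions_for_invariance(
                bd, b_list=[b], n_rotations=n_rotations, seed=seed
            )
            rows.append({"encoding": name, "b_ms_um2": b, "min_dirs": n})
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(outdir, "min_dirs_vs_b.tsv"), sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, grp in df.groupby("encoding"):
        ax.plot(grp["b_ms_um2"], grp["min_dirs"], "o-", label=name)
    ax.set(xlabel="b (ms/um^2)", ylabel="min directions (CV < 0.01)")
    ax.legend()
    fig.savefig(os.path.join(outdir, "fig.png"), dpi=120)
    plt.close(fig)
    _write_manifest(outdir, "fig5a", {"n_rotations": n_rotations, "b_list": b_list}, seed, t0)


def fig5b(outdir: str, seed: int = 0, snr: float = 150.0, n_repeats: int = 10, counts=None, **kw):
    """Fitted power-law exponent vs number of encoding directions."""
    t0 = time.time()
    counts = list(counts) if counts is not None else [10, 15, 20, 30, 45, 60, 90]
    tissue = synthetic.TissueModel(D_e_perp=0.75, radius_hist=default_radius_histogram(eta=1.5))
    rows = []
    rng = np.random.default_rng(seed)
    for bd, name in [(1.0, "LTE"), (-0.5, "PTE")]:
        for n in counts:
            protocol = encoding.build_protocol("sim21", b_delta=bd, n_dirs=n, seed=seed)
            clean = synthetic.simulate_voxel(tissue, protocol)
            alphas = []
            for _ in range(n_repeats):
                noisy = synthetic.add_rician_noise(clean, 1.0 / snr, seed=int(rng.integers(2**31)))
                ds = synthetic.DWIDataset(protocol=protocol, signals=noisy.reshape(1, -1))
                shell_b, _, curves = analysis.powder_average(ds)
                alphas.append(analysis.fit_powerlaw(shell_b, curves[0]).alpha)
            rows.append(
                {
                    "encoding": name,
                    "n_dirs": n,
                    "alpha_mean": float(np.mean(alphas)),
                    "alpha_sd": float(np.std(alphas, ddof=1)),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(outdir, "alpha_vs_dirs.tsv"), sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, grp in df.groupby("encoding"):
        ax.errorbar(grp["n_dirs"], grp["alpha_mean"], yerr=grp["alpha_sd"], label=name, capsize=2)
    ax.set(xlabel="number of directions", ylabel="fitted alpha")
    ax.legend()
    fig.savefig(os.path.join(outdir, "fig.png"), dpi=120)
    plt.close(fig)
    _write_manifest(outdir, "fig5b", {"snr": snr, "counts": counts}, seed, t0)


def _sweep_figure(outdir, df, xlabel):
    fig, ax = plt.subplots(figsize=(6, 4))
    for bd, grp in df.groupby("b_delta"):
        name = {1.0: "LTE", -0.5: "PTE"}.get(bd, f"b_delta={bd}")
        ax.errorbar(grp["f3"], grp["alpha_mean"], yerr=grp["alpha_sd"], label=name, capsize=2)
    ax.set(xlabel=xlabel, ylabel="fitted alpha")
    ax.legend()
    fig.savefig(os.path.join(outdir, "fig.png"), dpi=120)
    plt.close(fig)


def fig5c(outdir: str, seed: int = 0, snr: float = 150.0, n_repeats: int = 20, f3_grid=None, **kw):
    """Power-law exponent vs still-water (dot) signal fraction."""
    t0 = time.time()
    f3_grid = list(f3_grid) if f3_grid is not None else [0.0, 0.005, 0.01, 0.015, 0.02]
    df = analysis.sweep_fraction("dot", f3_grid, snr=snr, n_repeats=n_repeats, seed=seed)
    df.to_csv(os.path.join(outdir, "alpha_vs_dot_fraction.tsv"), sep="\t", index=False)
    _sweep_figure(outdir, df, "dot signal fraction f3")
    _write_manifest(outdir, "fig5c", {"snr": snr, "f3_grid": f3_grid, "n_repeats": n_repeats}, seed, t0)


def fig5d(outdir: str, seed: int = 0, snr: float = 150.0, n_repeats: int = 20, f3_grid=None, **kw):
    """Power-law exponent vs restricted-sphere (R_s = 8 um) signal fraction."""
    t0 = time.time()
    f3_grid = list(f3_grid) if f3_grid is not None else [0.0, 0.05, 0.1, 0.15, 0.2]
    df = analysis.sweep_fraction("sphere", f3_grid, snr=snr, n_repeats=n_repeats, seed=seed)
    df.to_csv(os.path.join(outdir, "alpha_vs_sphere_fraction.tsv"), sep="\t", index=False)
    _sweep_figure(outdir, df, "sphere signal fraction f3")
    _write_manifest(outdir, "fig5d", {"snr": snr, "f3_grid": f3_grid, "n_repeats": n_repeats}, seed, t0)


def fig6_synthetic(outdir: str, seed: int = 0, snr: float = 150.0, shape=(12, 12, 3), **kw):
    """Alpha maps and per-tissue histograms on a synthetic labelled phantom."""
    t0 = time.time()
    import nibabel as nib

    layout = np.full(shape, "background", dtype=object)
    layout[1 : shape[0] // 3] = "CSF"
    layout[shape[0] // 3 : 2 * shape[0] // 3] = "GM"
    layout[2 * shape[0] // 3 : shape[0] - 1] = "WM"
    protocol = encoding.build_protocol("sim21", b_delta=-0.5, seed=seed)
    ds = synthetic.make_phantom_volume(layout, synthetic.tissue_presets(), protocol, snr_b0=snr, seed=seed)
    maps = analysis.alpha_map(ds)
    for key in ("alpha", "beta", "bic"):
        nib.save(
            nib.Nifti1Image(maps[key].astype(np.float32), np.eye(4)),
            os.path.join(outdir, f"{key}.nii.gz"),
        )
    hist = analysis.alpha_histogram(maps, layout)
    hist.to_csv(os.path.join(outdir, "alpha_by_tissue.tsv"), sep="\t", index=False)
    fig, axp = plt.subplots(1, 2, figsize=(9, 4))
    im = axp[0].imshow(maps["alpha"][:, :, shape[2] // 2].T, vmin=0, vmax=3, cmap="viridis")
    fig.colorbar(im, ax=axp[0], label="alpha")
    for _, row in hist.iterrows():
        edges = np.asarray(row["hist_edges"])
        axp[1].stairs(row["hist_counts"], edges, label=row["label"])
    axp[1].set(xlabel="alpha", ylabel="voxels")
    axp[1].legend()
    fig.savefig(os.path.join(outdir, "fig.png"), dpi=120)
    plt.close(fig)
    _write_manifest(outdir, "fig6-synthetic", {"snr": snr, "shape": list(shape)}, seed, t0)


EXPERIMENTS = {
    "fig1": fig1,
    "fig3": fig3,
    "fig4": fig4,
    "fig5a": fig5a,
    "fig5b": fig5b,
    "fig5c": fig5c,
    "fig5d": fig5d,
    "fig6-synthetic": fig6_synthetic,
}


def run_experiment(name: str, outdir: str, seed: int = 0, **config):
    """Run one named experiment recipe; unknown names raise with the list of
    valid ones."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; valid: {sorted(EXPERIMENTS)}")
    os.makedirs(outdir, exist_ok=True)
    EXPERIMENTS[name](outdir, seed=seed, **config)
    return outdir
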