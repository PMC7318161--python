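# powderlaw

Powder-averaged diffusion-MRI signal analysis under axisymmetric b-tensor
encoding — linear (LTE), planar (PTE), spherical (STE), and every shape in
between.

## The problem

At high diffusion weighting the direction-averaged (powder-averaged) white
matter signal measured with conventional linear encoding decays as a power
law, S ∝ 1/√b, the fingerprint of water confined to "sticks" (axons with
negligible perpendicular diffusivity). Planar encoding is predicted to decay
as 1/b under the same geometry, and a complete analysis of the axisymmetric
b-tensor B = (b/3)(1-b_Δ)I + b·b_Δ·ggᵀ shows a power law exists **only** for
three pairings: LTE+stick (α = 1/2), PTE+stick (α = 1), and LTE+pancake
(α = 1); every other shape/geometry combination decays exponentially. The
different exponents let LTE and PTE cross-validate stick-like geometry in
vivo.

`powderlaw` implements this theory and the simulation study around it, for
researchers in diffusion-MRI microstructure:

- closed-form powder averages of Gaussian compartments for any b_Δ, with a
  numerically stable Dawson-function branch for the imaginary-erf regime;
- the high-b asymptotic series of the PTE stick signal
  S ≈ (1/bD)Σ(2k-1)!!/(bD)^k, its optimal truncation (N ≤ ⌊bD⌋) and
  minimum-terms tables;
- the power-law-existence classifier, validated against measured log-log
  slopes;
- restricted compartments (van Gelderen cylinders, spheres, the zero-radius
  "dot") with r²-weighted radius-histogram averaging and shrinkage factors;
- a three-compartment Watson-dispersed synthetic-data generator with Rician
  noise (b0-SNR 150) and labelled phantom volumes (NIfTI + bval/bvec/bdelta
  I/O);
- the analyses: powder averaging, trust-region power-law fits S = β·b^(-α)
  with BIC, Rayleigh-background σ/SNR estimation, noise-floor limits on b·D
  per encoding, minimum-direction counts for rotational invariance, and
  dot/sphere sensitivity sweeps with voxelwise α maps.

See `docs/methods.md` for the model, numerical choices, and limitations.

## Worked example

Simulate a noise-free planar-encoded voxel with the default tissue
(f₁ = 0.65, D_a∥ = 2 μm²/ms, κ = 11, 21 shells × 60 directions), powder
average it, and fit the power law over 7000–10 000 s/mm²:

```sh
powderlaw simulate --out wk --snr 0 --seed 0 --bdelta=-0.5
powderlaw powder wk/dwi.nii.gz --out wk/curve.tsv
powderlaw fit wk/curve.tsv
```

prints

```json
{
 "alpha": 1.1508466516615088,
 "beta": 0.4874972296713656,
 "rss": 4.436471931471509e-08,
 "bic": -128.245299799126,
 "n_points": 7,
 "converged": true
}
```

The exponent near 1 is the planar-encoding stick signature; it sits slightly
above 1 (and β above f/D_a∥ = 0.325) because on this narrow window the
higher-order series terms and the residual extra-axonal signal steepen the
fit — exactly the bias the wide-window analysis quantifies. The noise-floor
analysis,

```sh
powderlaw noise-floor --snr 50
```

prints `{"LTE": 312.5, "PTE": 21.08, "STE": 8.98, ...}` — the maximum
dimensionless b·D each encoding can reach at b0-SNR 50 before the powder
average hits twice the Rayleigh background mean, illustrating why LTE
(∝ SNR²) tolerates far stronger weighting than PTE (∝ SNR) or STE
(logarithmic).

Figure-style experiment recipes (`powderlaw experiment fig1|fig3|fig4|fig5a|
fig5b|fig5c|fig5d|fig6-synthetic --out DIR`) write TSV tables, PNG figures,
and a JSON manifest; rerunning with the same seed reproduces the tables
byte-for-byte.

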