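# Methods

## Scope and model

`powderlaw` studies the direction-averaged ("powder-averaged") diffusion-MRI
signal at high b-values under axisymmetric b-tensor encoding. An encoding
unit is the tensor

    B = (b/3)(1 - b_Δ) I + b b_Δ g gᵀ,

with b = trace(B) the diffusion weighting, g the symmetry axis, and the shape
parameter b_Δ = (b_∥ - b_⊥)/(b_∥ + 2 b_⊥) ∈ [-1/2, 1]: b_Δ = 1 is linear
(LTE), 0 spherical (STE), -1/2 planar (PTE) encoding. Internally b is carried
in ms/μm² so that b·D is dimensionless with diffusivities in μm²/ms; all file
I/O (FSL `.bval`) is in s/mm² with an exact ×10⁻³ conversion. A `.bdelta`
sidecar (one shape value per volume) accompanies `.bval`/`.bvec`.

For an axially symmetric Gaussian compartment (D_∥, D_⊥), the average of
exp(-tr(B·D)) over uniformly distributed encoding directions has the closed
form

    S(b) = √π · exp(-(b/3)(D_∥ + 2D_⊥ - b_Δ(D_∥ - D_⊥)))
           · erf(√z) / (2√z),      z = b b_Δ (D_∥ - D_⊥).

For z < 0 the error function continues to the imaginary error function; we
evaluate that branch through the Dawson function D(y) (erfi(y) =
2e^{y²}D(y)/√π), which is overflow-free at any weighting — the naive
e^{-y²}·erfi(y) product overflows beyond b·D ≈ 1400 and loses precision much
earlier. Within |z| < 10⁻⁴ a fourth-order series of the erf(√z)/√z kernel
bridges the two branches continuously (verified to |ΔS| < 10⁻⁸ across
b_Δ = ±10⁻⁶). A `log_powder_signal` path keeps the whole computation in log
space for slope measurements at extreme weightings.

The planar-encoded stick (D_⊥ = 0) reduces to S = D(x)/x with x = √(bD_∥/2)
and admits the asymptotic expansion

    S ≈ (1/bD_∥) Σ_{k=0..N} (2k-1)!! / (bD_∥)^k,

with the convention (-1)!! = 1 so the k = 0 term is 1/(bD_∥). The series is
asymptotic (divergent in N at fixed bD): the minimum-error truncation order
never exceeds ⌊bD_∥⌋, and `min_terms_table` caps its search there,
marking thresholds that no admissible order reaches. Two boundary cells of
the reference tabulation are not reproducible under the normalized error
|S - Ŝ|/S as defined (e.g. at bD = 7 the smallest attainable error is 0.0115,
just above the 0.01 threshold, at N = 3); the tests compare such cells with
±1 tolerance and log, rather than fail, the residual disagreements.

A power law S ∝ b^(-α) at large b exists for exactly three encoding/geometry
pairings — LTE+stick (α = 1/2), PTE+stick (α = 1), LTE+pancake (α = 1) —
because the exponential prefactor must vanish, which forces
D_⊥/D_∥ = (b_Δ-1)/(b_Δ+2) onto one of its boundary solutions.
`powerlaw_condition` classifies with tolerance 10⁻⁹ on the shape and
diffusivity equalities; the acceptance tests verify each verdict against the
numerically measured log-log slope (stable and equal to -α where a power law
exists, steepening without bound where not).

## Restricted compartments

Finite radii use the Gaussian phase approximation with the standard
pulsed-gradient Bessel-root series: for a cylinder of radius r, roots μ_m of
J₁′, modes λ_m = D₀(μ_m/r)², and waveform factor

    2λδ - 2 + 2e^{-λδ} + 2e^{-λΔ} - e^{-λ(Δ-δ)} - e^{-λ(Δ+δ)},

the perpendicular log-attenuation maps to an effective diffusivity
D_⊥eff = -ln E_⊥ / (δ²(Δ - δ/3)) which is then composed with the b-tensor
through the Gaussian closed form above. This keeps the full b and b_Δ
dependence while the radius enters only through D_⊥eff, and reduces exactly
to the stick at r = 0. Spheres use the same series with roots of the
spherical j₁′ and denominator (μ² - 2); being isotropic, the sphere
attenuation exp(-b·D_eff) is independent of shape and direction, and R_s = 0
is the "dot" (still water, unit signal at all b). Defaults: 20 roots with a
convergence guard (last term < 10⁻³ of the sum raises), timing δ/Δ =
15/30 ms (the source acquisition specifies only TE, not pulse timings; these
are representative spin-echo values and are configurable), D₀ = 2 μm²/ms.
The series is validated against an independent numerical time-integration of
the pulsed-gradient autocorrelation per mode (10⁻⁴ relative) and against its
physical limits (D_⊥eff → 0 as r → 0, → D₀ for r² ≫ D₀Δ; note the exact
free-diffusion limit requires the mode-sum identity Σ 1/(μ_m²-1) = 1/2).
Apparent restricted diffusivity *decreases* with diffusion time Δ; the test
suite asserts that direction (non-increasing in Δ).

Axon-radius heterogeneity: the cylinder signal is averaged over a radius
histogram with r² (volume) weights after scaling radii by a shrinkage factor
η ∈ {0, 1, 1.5}; η = 0 collapses to zero-radius sticks. The packaged default
histogram is a synthetic stand-in — 10 equal-probability-range bins of a
lognormal with median 0.6 μm and σ_log = 0.45, a generic small-axon white
matter distribution — because the histology histogram the simulation study
drew on is not published in usable form. It is fully overridable via a
two-column TSV.

## Synthetic data generator

The simulator produces the study conditions: 60 electrostatic-repulsion
gradient directions per shell, 21 b-values 0–10 000 s/mm² (step 500) or 10
shells 1000–10 000 s/mm² (step 1000) with interleaved b0s, per-shell shape
b_Δ, and the three-compartment Watson voxel

    S/S0 = f₁ ∫ W(n) S_cyl(n) dn + f₂ ∫ W(n) S_ec(n) dn + f₃ S_sph,

with defaults f₁ = 0.65, D_a∥ = D_e∥ = 2 μm²/ms, D_e⊥ ∈ {0.25, 0.5, 0.75}
(0.5 as the single default), κ = 11, sphere radius 8 μm or dot. When a third
fraction f₃ is introduced for the sensitivity sweeps, f₁ and f₂ shrink
proportionally so the fractions stay normalized (the renormalization rule is
our choice; nothing in the source specifies one). The Watson density
exp(κ(μ·n)²)/(4π M(½,3/2,κ)) is evaluated through the Kummer transform
M(½,3/2,κ) = e^κ M(1,3/2,-κ) so it stays finite at any concentration; its
normalizer uses `scipy.special.hyp1f1`.

Orientation integrals run on a Gauss-Legendre(cos θ) × uniform(φ) product
quadrature, exact for spherical harmonics to the requested degree. The
degree escalates with concentration as 35 + ⌈9√κ⌉ (a Watson density of
concentration κ has polar caps of angular width ~1/√κ that the polar nodes
must resolve); this keeps ∫W = 1 to better than 10⁻⁸ from κ = 0 through
κ = 10⁴, where the quadrature reproduces the coherent-stick limit to 10⁻⁶.
Passing an explicitly low degree with κ > 50 raises rather than silently
under-integrating.

Noise is Rician: S_n = √((S+N_r)² + N_i²) with independent zero-mean
Gaussians of standard deviation σ; in b0-normalized units σ = 1/SNR_b0 with
SNR_b0 = 150 as the study condition. Background (zero-signal) voxels of the
phantom generator therefore follow a Rayleigh distribution, which the
σ-estimator inverts through its mean (σ̂ = √(2/π)·⟨M_background⟩). Every
stochastic call takes an explicit seed; run manifests record seeds and
parameters.

What the generator does *not* emulate: T2/TE weighting, partial-volume
mixing, exchange/permeability, axonal undulation, imaging artifacts (Gibbs,
eddy currents, motion) and realistic head geometry. Tests passing on these
phantoms therefore validate the signal theory and the estimation chain, not
robustness to real-data confounds.

## Analyses

*Power-law fit.* S = β·b^(-α) (b in ms/μm²) by bounded trust-region least
squares in linear signal space from the fixed start (α, β) = (1, 0.2),
bounds α ∈ [0, 5], β ∈ [0, 10]; default window 7000–10 000 s/mm²;
BIC = n·ln(RSS/n) + 2·ln n. Fits with a parameter pinned at a bound (within
10⁻⁴) are flagged not-converged — this catches degenerate flat curves (α→0)
and exponential decays that exhaust the α bound. On the narrow 7–10 ms/μm²
window the noise-free planar stick with f = 0.65, D = 2 fits to
(α, β) ≈ (1.10, 0.43): the higher-order series terms bias the narrow-window
fit above the asymptotic (1, f/D = 0.325), which is recovered to 2% only
when the window is widened to b·D ≳ 200.

*Noise floor.* The criterion "signal = twice the Rayleigh background mean",
S·SNR_b0 = 2√(π/2) ≈ 2.5066, applied to each encoding's stick powder
average by bracketed root finding. This threshold reproduces all three
reference values at SNR = 50 (≈312.5 LTE, ≈21.1 PTE, ≈8.98 STE; STE has the
closed form 3·ln(SNR/2√(π/2))). The corresponding SNR = 150 triple printed
in the source (15 625, 100, 16) is not consistent with any single threshold
and is not asserted. Scaling: SNR² for LTE (from low SNR), SNR¹ for PTE once
bD ≳ 18 (below that the 1/bD series corrections flatten the measured slope
to ~0.95), logarithmic for STE.

*Minimum directions for rotational invariance.* Gaussian tensor signal
S = exp(-tr(BD)) with an axisymmetric tensor solved from MD = 1.0 μm²/ms and
FA = 0.95; the tensor axis is rotated over 512 uniformly distributed
orientations (antipodal-repulsion axes with a golden-angle roll — the
original construction is unpublished); per shell the powder average's
CV = SD/mean across rotations must fall below 0.01 at every shell in
7000–10 000 s/mm² (step 1000), and the smallest direction count achieving
this is reported (ascending search, capped at 200). Direction sets minimize
the antipodal Coulomb energy Σ 1/sin²θ_ij from 10 seeded restarts
(deterministic per seed; a Fibonacci-sphere fallback exists for speed).
With this construction the counts are ≈59 (PTE) and ≈60–61 (LTE), stable
across seeds. The reference analysis reports 45 and ≈80. Our procedure
reproduces the cited method's published counts at b ≤ 4000 s/mm²
(PTE ≈ 24 vs 15–20; LTE ≈ 29 vs 20–32, same ordering), and cross-checks
rule out gross construction errors (full-sphere Thomson sets are 20–50×
worse; Jones-style antipodal 1/r sets shift counts by <5). The residual
high-b divergence evidently traces to the unpublished direction-set
construction of the reference; we report our measured counts rather than
tuning the construction toward the printed ones. The LTE count does exceed
the PTE count and stays ≤80 under all seeds tried.

*Dot/sphere sensitivity sweeps.* For f₃ grids the voxel is simulated on the
21-shell protocol per encoding shape (D_e⊥ = 0.75, η = 1.5, SNR = 150,
20 noise repeats), powder-averaged, and fitted over 7–10 ms/μm²; mean ± SD
of α across repeats is tabulated. The planar exponent is far more sensitive
to a still-water fraction than the linear one (at f₃ = 0.02 the dot is ~66%
of the planar top-shell signal but only ~15% of the linear one), matching
the reference's qualitative account. Quantitatively, however, a 2% constant
offset necessarily flattens the linear log-slope by ~10% — even noise-free —
so the reference's "≤2% change" bound for LTE is not attainable under these
conditions and the corresponding acceptance check is left failing by design
rather than weakened. The restricted-sphere sweep (R_s = 8 μm) raises the
planar α monotonically, as expected.

*α maps.* Voxelwise fits with per-voxel failure isolation (no-b0 or
nonpositive-window voxels masked NaN), optional per-label histograms. On the
synthetic phantom the WM-like region centres near α = 1 under planar
encoding and the GM-like (stick+sphere) region near 1.7; the CSF-like region
sits at the noise floor at these b-values, so its fitted exponent collapses
toward 0 with noise (≫1 only noise-free).

## Problem sizes and determinism

Defaults are the study conditions (60 directions, 21 shells, 512 rotations,
SNR 150, 20 repeats). The phantom used in tests is 8×8×4; the figure-style
recipe uses 12×12×3. All stochastic stages are seeded; repeated runs with
the same seed produce byte-identical tables.

## Known limitations

- Single-voxel Gaussian-compartment theory: no exchange, time-dependent
  extra-axonal kurtosis, or non-axisymmetric b-tensors.
- The sphere-under-b-tensor attenuation is our GPA reconstruction (the
  reference's exact expression is unavailable); the sphere sweep is asserted
  qualitatively (monotone α increase), not point-wise.
- The default radius histogram is synthetic (see above); radius-dependent
  results shift with the histogram supplied.
- Direction-count results depend on the direction-set construction; see the
  minimum-directions discussion above.
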