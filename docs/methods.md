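# Methods

## Signal model

A voxel contains one or two restricted (intra-axonal) populations and one
hindered (extra-axonal) compartment. All quantities are in µm, ms, µm²/ms;
b-values in ms/µm² (1 ms/µm² = 1000 s/mm²); gradient amplitudes in mT/m,
back-computed from b via b = γ²g²δ²(Δ − δ/3) with γ = 2.675×10⁸ rad s⁻¹ T⁻¹.

**Restricted compartment.** Water inside impermeable parallel cylinders.
Perpendicular to the axis the echo attenuation follows the van Gelderen
Gaussian-phase-distribution (GPD) expression for rectangular pulses,
truncated at the first 20 roots of J₁′; with 20 terms the truncation error
is far below the 10⁻⁸ level for every timing in the supported protocols.
The GPD choice (rather than the short-pulse approximation) matters because
the pulse widths here (5–7 ms) are not short relative to the intracylinder
diffusion time. The expression is validated against an independent
Monte-Carlo random walk in a reflecting disc (1% agreement; see the test
suite's oracle module). Axially the decay is Gaussian with the intra-axonal
axial diffusivity D_a.

**Diameter distribution.** Cylinder diameters follow a discretized Poisson
distribution: grid d_k = k·step with pmf rate λ/step, so the count-weighted
mean diameter equals λ. The default step is 1.0 µm with truncation at
10 µm, which makes the distribution exactly d ~ Poisson(λ) on integer
micrometres — one parameter controls both mean and dispersion (variance λ).
A finer step would shrink the variance toward zero (variance = λ·step) and
destroy the large-diameter tail that carries most of the signal
(attenuation grows ≈ r⁴), making the diameter index practically
unidentifiable at in-vivo SNR; the integer-µm grid is therefore a modelling
choice, not a numerical discretization. Signal weights across bins default
to the raw pmf ("count" weighting, keeping "mean caliber = λ" literally
true); cross-sectional d² ("volume") weighting is available as a flag.

**Proxy calibre scale.** A value d on the distribution grid enters the GPD
kernel as the cylinder *radius* (kernel diameter 2d, `diameter_scale=2`).
This follows the AxCaliber-family lineage, whose restricted-cylinder
formulas are written in radius, and it is the convention under which the
recovery simulations reproduce the published sensitivity of the method; it
also means the reported λ overestimates true anatomical caliber by roughly
a factor two, consistent with the well-documented gap between MRI
axon-diameter indices and histology. The strict physical reading
(grid value = diameter, `diameter_scale=1`) is available everywhere; the
standalone attenuation function `restricted_perpendicular_attenuation` is
always strictly physical (its argument is the cylinder diameter).

**Hindered compartment.** Axially symmetric Gaussian diffusion with
apparent diffusivity D⊥(Δ) + (D∥ − D⊥(Δ))cos²θ, where
D⊥(Δ) = D⊥(Δ_MIN) + slope·(Δ − Δ_MIN), clipped at zero. With two restricted
populations the hindered axis is the principal eigenvector of the
fraction-weighted dyadic mean of the population orientations. An
alternative structural-disorder form D_∞ + A·ln(Δ/δ)/Δ (anchored at Δ_MIN)
is implemented for BIC comparison.

**STEAM.** Stimulated-echo data carry an extra mono-exponential decay
exp(−TM/T1) over the mixing time; TM defaults to Δ − δ when a protocol does
not specify it. A bi-exponential T1 variant exists only inside the T1
model-selection routine.

**Noise.** Magnitude noise is Rician. The analytic expectation
σ√(π/2)·[(1+x)·i0e(x/2) + x·i1e(x/2)], x = ν²/2σ², is evaluated through
exponentially scaled Bessel functions (stable at any SNR; matches direct
quadrature to 10⁻⁶). The generator adds noise as |S + n₁ + i·n₂|.

## Fitting cascade

1. **DTI** — log-linear least squares on the shortest-Δ, lowest-b shell plus
   b0s; supplies FA and the principal direction. At b = 2000 s/mm² and SNR
   ~17 the principal direction is good to ~6° (median), which is accurate
   enough to initialize the next stage.
2. **CHARMED stage** (shortest Δ only) — sticks-plus-hindered fit for
   orientations, fractions, axial diffusivities, with the hindered radial
   diffusivity pinned to the tortuosity value D_a(1−f)/(1+f). Estimates
   are used as fixed values / initializations downstream.
3. **AxCaliber stage A** — frees {λ, fractions, slope, s0, σ, T1 (STEAM)}
   on the full multi-Δ data; the radial diffusivity at Δ_MIN stays pinned
   to the tortuosity of the *current* fraction. Optionally (`fit_d_intra`)
   D_a is freed too, with the extra-axonal axial diffusivity tied to it —
   the parameterization matching the model's fitted-parameter list, which
   carries no separate extra-axonal axial term.
4. **Stage B (release)** — everything frozen at stage-A values except
   {D⊥(Δ_MIN), σ}, refitted jointly. Releasing a constraint cannot worsen
   the optimum; the implementation enforces this up to optimizer tolerance.

The objective throughout is least squares between measured magnitudes and
the Rician expected magnitude with σ free — consistent near the noise floor
where Gaussian least squares is biased. (On completely signal-free voxels
this mean-based objective still under-reads σ by ~12%, because the mean
model can absorb part of the floor; the limitation is documented rather
than patched, as such voxels are masked in practice.) Optimization uses
bounded trust-region least squares with multi-start over λ (defaults
{1, 2.5, 4} µm; the recovery experiment uses {1, 3.5}, which straddles the
same two basins at two-thirds the cost with measurably identical results);
tolerance 10⁻⁸ on the cost, at most 500 evaluations per stage.

**Bounds.** λ ∈ [0.1, 6] µm; f ∈ [0, 0.9]; diffusivities ∈ [0, 3] µm²/ms;
slope ∈ [−0.02, 0.02] µm²/ms per ms; σ ∈ (0, max signal]; T1 ∈ [0.1, 5] s.
The λ upper bound is 6 rather than the grid's 10 µm because beyond ~6 the
truncated Poisson loses more than the distribution's own 10⁻⁶ mass
tolerance and the perpendicular signal is fully saturated, so larger values
are never interpretable — they only serve as spurious attractors for noisy
fits.

**Model selection.** BIC = k·ln(n) − 2·logL with a Gaussian likelihood at
the ML residual variance, computed identically for the models being
compared; a relative floor on the residual sum of squares makes noise-free
comparisons reduce to the parameter-count penalty. Ties break toward the
simpler/linear model.

## Recovery simulations

Ground truth per draw: diameter proxy λ ~ U(0.5, 5) µm, restricted fraction
~ U(0.1, 0.5), intra-axonal axial diffusivity ~ U(0.7, 2.2) µm²/ms (narrow
variant: 1.7–2.2), orientation uniform on the sphere, slope ~ U(−0.005, 0)
µm²/ms², extra-axonal axial diffusivity equal to the intra-axonal one,
radial diffusivity at Δ_MIN from the tortuosity relation, s0 = 1,
σ = 1/SNR (17.3 human / 11.2 rat), T1 = 1700 ms for STEAM. The human
condition uses the 273-direction PGSE protocol (1 b0 + 30×b2000 + 60×b4000
per Δ ∈ {17, 35, 61} ms, δ = 7 ms); the rat condition the 132-measurement
STEAM protocol (3 b0 + 15 + 15 per Δ ∈ {15, 25, 40, 60} ms, δ = 5 ms).
Directions are generated per shell by seeded electrostatic repulsion of
antipodal charge pairs.

**Estimator.** The default recovery mode is *conditioned*: the fiber
orientation and restricted fraction — the quantities determined by the
geometry stages of the cascade — are supplied, and {λ, D_a (extra-axial
tied), slope, s0, σ, T1 for STEAM} are refitted per noisy repetition, with
the D_a search restricted to the sampling range of the condition. This
isolates the diameter estimator itself. The choice is deliberate: the
single-repetition profile likelihood has a flat ridge along which λ and f
trade off almost freely (a 4-µm change in λ is compensated by a ~0.02
change in f at these SNRs), so a fully blind per-repetition fit measures
mostly ridge noise — its truth-fit correlation tops out near 0.55/0.35
(human/rat) even with oracle values for every other parameter, whereas the
conditioned estimator reaches the regime the repetition-averaging behaviour
of the method implies (single-rep errors shrinking ~√10 under 10-rep
averaging). The blind mode remains available (`mode="blind"`) for users who
want the end-to-end cascade variance.

**Summary statistics.** `r_single` correlates truth with the
first-repetition estimate; `r_mean` with the per-draw mean over
repetitions (fitting each repetition and averaging estimates, not fitting
averaged signals). Typical desk-scale values (2000 draws, or 500×10 for
the averaged conditions, one CPU, ~10 min total): ~0.90 human single-rep,
~0.73 rat single-rep, ~0.98/~0.95 after 10-repetition averaging, and
~0.90/~0.75 for the narrow-diffusivity variants. The full-scale study
design (10⁵ draws) changes only the sampling error of these correlations.

## Tract phantom

A 32×32×`n_slices` volume with two mirrored fimbria-like arcs in the axial
plane, orientations along the local tangent, constant restricted fraction
0.4, D_a = 1.7 µm²/ms, slope −0.003, and a position-indexed λ profile:
control side flat at 2 µm, "injected" side elevated by 1 µm posterior to
the tract midpoint. Background voxels carry isotropic free-water-like
signal and are excluded from fitting. Rician noise at SNR 11.2 matches the
preclinical acquisition.

Along-tract profiles are extracted by averaging the signals of each tract
cross-section (identical geometry within a section by construction) and
fitting the joint model with the skeleton tangent as orientation — the
along-tract analogue of sampling a parameter map along streamlines, with
the averaging moved before the ill-conditioned fit to stabilize it.
Profiles are compared with pointwise paired t tests across phantom
instances, BH-FDR corrected, plus a whole-tract paired test on per-subject
means. With 10 instances at SNR 11.2 the +1 µm elevation is detected at
most posterior positions with no anterior false positives.

What the phantom does *not* emulate: partial volume at tract borders,
orientation dispersion (deferred: the model treats fibers as perfectly
parallel), spatially varying fractions/diffusivities, susceptibility or
motion artefacts. Passing phantom tests therefore demonstrate estimator
and statistics correctness under the model's own assumptions, not
robustness to real-data confounds.

## Numerical and design notes

* Orientation antipodal sign is canonicalized to the positive-z hemisphere
  (ties to positive x).
* Degenerate voxels (all-zero, or nonpositive mean b0) are skipped and NaN
  in output maps; volume fitting results are independent of voxel visit
  order and of the number of workers.
* The per-voxel GPD factor is precomputed per unique (δ, Δ) pair; when D_a
  is free it is linearly interpolated from a 61-node table over
  [0.05, 3.05] µm²/ms, cached per scheme layout (interpolation error is
  orders of magnitude below the noise level).
* b0 threshold: 50 s/mm². Scheme sidecars (FSL-dialect bval/bvec plus a
  per-volume `bdelta` table: Δ_ms δ_ms TM_ms SEQ, `# bdelta v1` header)
  round-trip bit-exactly.
* The CLI's `recover --config` accepts a YAML file whose keys are the
  `SimulationConfig` field names (`n_draws`, `n_reps`, `snr`,
  `scheme_preset`, `d_intra_range`, `diameter_range`, `fraction_range`,
  `slope_range`, `t1`, `seed`); every run writes a `provenance.json`
  (package version, seed, config echo) alongside its outputs.
* Single seedable RNG threaded through all stochastic operations; the
  recovery experiment and phantom are byte-reproducible under a fixed
  configuration.

## Known limitations

* No fiber orientation dispersion, exchange, or non-rectangular gradient
  waveforms.
* The diameter proxy is only weakly identifiable below ~1.5 µm at these
  gradient strengths; estimates there are dominated by the prior range.
* Blind per-voxel single-repetition fitting of λ and f jointly is
  ill-conditioned (see above); per-voxel maps at low SNR should be read as
  regularized indices, and group comparisons should rely on paired designs
  as the phantom analysis does.
* T1 estimation from STEAM mixing times spanning only ~50 ms is weak; the
  T1 term mainly absorbs block-level scaling.
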