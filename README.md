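# axdiam

Axonal diameter mapping from multi-shell, multi-diffusion-time diffusion
MRI, for microstructure-imaging researchers who want a self-contained,
testable implementation of the AxCaliber-style pipeline with a
time-dependent extra-axonal compartment — including the synthetic-data
machinery needed to evaluate it without any scanner data.

## The model

The per-voxel magnitude signal is a two-compartment prediction

```
S(b, u, Δ, δ) = S0 · [ Σᵢ fᵢ · Rᵢ(b, u, Δ, δ) + (1 − Σᵢ fᵢ) · H(b, u, Δ) ] · e^(−TM/T1)
```

* **Restricted compartment** `Rᵢ`: water inside impermeable parallel
  cylinders along orientation `uᵢ` — Gaussian axial decay `exp(−b·D_a·cos²ψ)`
  times the van Gelderen Gaussian-phase-distribution (GPD) attenuation
  perpendicular to the axis, averaged over a discretized Poisson diameter
  distribution whose single parameter λ (µm) sets both mean and dispersion.
  λ is the *MRI axonal diameter proxy* reported in the maps.
* **Hindered compartment** `H`: axially symmetric Gaussian diffusion whose
  radial diffusivity depends linearly on the diffusion time,
  `D⊥(Δ) = D⊥(Δ_MIN) + slope·(Δ − Δ_MIN)`.
* **STEAM acquisitions** carry a mono-exponential T1 decay over the mixing
  time; **Rician noise** is modelled analytically (the fit matches the
  expected magnitude, with the noise level σ a free parameter).

Fitting follows a cascade: DTI (lowest shell, shortest Δ) → CHARMED-style
stick fit at the shortest Δ (orientations, fractions, axial diffusivities)
→ AxCaliber stage with the extra-axonal radial diffusivity pinned to the
tortuosity value `D_a(1−f)/(1+f)` → a final stage that releases that
constraint and refits only the radial diffusivity and the noise term.
BIC comparisons select between the linear and a structural-disorder
`D_∞ + A·ln(Δ/δ)/Δ` time dependence, and between mono- and bi-exponential
T1 decay.

## Worked example

Simulate a recovery experiment on the 273-direction human protocol
(b = 2000/4000 s/mm², Δ = 17/35/61 ms, δ = 7 ms) at SNR 17.3:

```bash
axdiam recover --preset human_connectom --n-draws 200 --seed 42 --out recovery.csv
```

prints

```
n_draws=200 n_reps=1 preset=human_connectom snr=17.3: r_single=0.9158 r_mean=0.9158 (failed fits: 0)
```

`r_single` is the Pearson correlation between the ground-truth diameter
proxy of each simulated voxel (drawn uniformly from 0.5–5 µm, with
restricted fraction 0.1–0.5 and axial diffusivity 0.7–2.2 µm²/ms) and the
value refitted from a single Rician-noisy realization — i.e. how well a
single acquisition recovers the per-voxel diameter index under realistic
noise. The CSV holds one row per draw with the full truth/fit parameter
pairs.

The same machinery builds a two-hemisphere tract phantom (a fimbria-like
arc per hemisphere, with the diameter proxy elevated by 1 µm posterior to
the midpoint on one side) and compares the fitted along-tract profiles with
pointwise paired t tests under FDR correction:

```python
from axdiam import generate_tract_phantom, tract_profile_compare, TractProfilePair
from axdiam.synthetic import phantom_profiles
import numpy as np

profiles = [phantom_profiles(generate_tract_phantom(n_slices=2, snr=11.2, seed=s))
            for s in range(100, 110)]
left, right = map(np.array, zip(*profiles))
result = tract_profile_compare(TractProfilePair(np.arange(left.shape[1]), left, right))
print(result["table"][["position", "p_fdr", "reject"]])
```

Rejections concentrate in the posterior (elevated) half of the tract and
the whole-tract paired test is strongly significant, mirroring the
unilateral-injury contrast the method was designed to detect.

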