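# Methods

## The normative model

Cortical thickness at each vertex of a common triangulated surface is
regressed, over a healthy control cohort, on

    1 + age_c + sex + age_c·sex + handedness,   age_c = age − age_case

by ordinary least squares, independently per vertex. Age is centred on the
case's age, so the model must be refitted per case; the payoff is that the
intercept is directly the expected thickness of a reference subject (female,
right-handed) of exactly the case's age, and the case's design row reduces to
`[1, 0, sex, 0, handedness]`. Covariate coding (female=0/male=1,
right=0/left=1) is persisted inside the model object: coefficients are only
interpretable relative to a coding, and predictions refuse to mix schemes.

The case's per-vertex deviation is the studentized residual
`(actual − predicted) / controlSD`, with controlSD the control residual
standard deviation using the unbiased divisor n − rank(X). Two choices here
were genuinely open and are exposed as options with these defaults:

* **SD divisor** — n − rank (standard OLS); divisor n or n − 1 would shrink
  the SD by < 1.5% at n = 188.
* **Prediction-variance inflation** — the plain ratio is the default; the
  flag `inflate=True` multiplies the denominator by
  `sqrt(1 + x0'(X'X)⁻¹x0)` (Crawford–Howell-style) for out-of-sample cases.
  With 188 controls the inflation is ≈ 1.3% in SD, which is why the plain
  ratio's null deviations have pooled variance slightly above 1 (measured
  ≈ 1.07 at n = 50, within the expected [0.9, 1.15] band).

Rank-deficient designs (e.g. a single-sex cohort in a small simulation) are
fitted by minimum-norm least squares after a warning. Vertices with zero
residual SD (noise-free fixtures) are flagged missing and excluded from
inference rather than producing infinities.

## Random-field-theory inference

Under the null the deviation map is treated as a t field with ν = n − rank
degrees of freedom (at ν = 183 it is within a hair of Gaussian, but the t
densities are exact for any cohort size). The search region's resel counts
are computed from the actual analysed region: R₀ = its Euler characteristic
(V − E + F of the included submesh), R₁ = half its boundary length / FWHM
(zero for a closed surface), R₂ = area / FWHM².

* **Smoothness.** Control residuals are normalized to unit sum of squares
  per vertex; the mean over edges of the summed squared gradient estimates
  2(1 − ρ)/L², and FWHM = sqrt(4 ln 2 / g). A single global FWHM is used —
  non-stationary (per-vertex) smoothness is out of scope.
* **Peak-wise p.** `min(1, sides · Σ_d R_d ρ_d(t))`, the expected-EC bound,
  with `sides = 2` for two-sided inference.
* **Cluster-wise p.** Clusters are maximal connected components of
  suprathreshold vertices under mesh (edge) adjacency, with extent measured
  as summed barycentric vertex areas. Their corrected p uses the exponential
  extent approximation: with E[m] the expected cluster count (expected EC at
  the cluster-forming threshold) and E[N] the expected suprathreshold resel
  volume, `P(extent ≥ k) = exp(−k·E[m]/E[N])` and
  `p = 1 − exp(−sides·E[m]·P(extent ≥ k))`.
* **Defaults.** Cluster-forming threshold: the t quantile of uncorrected
  p = 0.001; sidedness: two-sided with per-sign clusters (deviation surveys
  should see thinning as well as thickening); α = 0.05. All are flags.

Monte-Carlo calibration (1000 null pseudo-cases, 188 controls, 2562-vertex
icosphere, noise FWHM three mean edge lengths) gives familywise error ≈
0.03–0.05 for both cluster- and peak-wise inference at nominal 0.05. The
expected-EC bound plus the discreteness of the mesh lattice make peak-wise
inference mildly conservative; that is the intended direction of error.

## The synthetic generator

The generator emulates the study conditions the pipeline targets: 188
controls, ages normal(52.2, 9.5²) truncated at 18 (an adult cohort selected
within 15 years of cases aged 43–54), 140/188 female, 169/188 right-handed.
Thickness maps are linear covariate effects plus a stationary Gaussian random
field produced by iterated neighbour-blend diffusion of white noise,
calibrated (against the same edge-gradient FWHM estimator, from a fixed probe
batch) to a target FWHM — by default three mean edge lengths — and scaled by
a noise SD of 0.2 mm. The cohort description the defaults emulate does not
include a thickness variance; 0.2 mm is a conventional morphometry-scale
choice. Default coefficient values (intercept 2.33–2.5 mm, age slope
−0.01 mm/yr, small sex/handedness effects) are morphometry-plausible
constants; the case simulations use intercept 2.33 mm so that the normative
prediction at the reference case (43-year-old right-handed female) is
2.33 mm, and inject delta = 0.72 mm = 3.05 − 2.33, the scale of effect the
method is meant to find. Injected patches are grown by breadth-first rings
(connected by construction) and tapered to delta/2 over the 1-ring collar.

What passing simulations do **not** show about real data: real thickness
fields are non-stationary (smoothness and variance vary over cortex), cases
and controls may come from different scanners (deliberately unmodelled), true
covariate effects are spatially varying and not exactly linear, and CIVET-
style processing artifacts are absent. The generator's stationarity matches
the assumption RFT itself makes, so the calibration results validate the
implementation, not the assumption.

Lesioned-volume phantoms are a smooth ellipsoidal head with geometric-
primitive lesions (voxels set to background); the template doubles as the
pre-lesion truth, which is what makes bit-exact compositing checks possible.

## Numerical and design choices

* Vertex indexing is 0-based everywhere, including the OBJ-style ASCII
  dialect (`f` records 0-based) — one convention, stated once. ASCII writers
  use shortest round-tripping decimals (`repr`), making write→read→write
  bit-stable; GIFTI containers round-trip to float32 (~1e-7 relative).
* Meshes with several connected components are rejected by default
  (`keep_largest=True` analyses the largest); RFT assumes one search region.
  Degenerate (zero-area) triangles are integrity errors.
* Cluster tables are deterministically ordered (descending |peak|, ties by
  peak vertex), so reruns are byte-identical.
* Diffusion smoothing near the target switches to smaller blend steps
  (λ 0.5 → 0.15) so single-field smoothing lands within 10% of the target.
* FWER simulations amortize cohorts: 1000 pseudo-cases share 20 independent
  cohorts (50 each). The FWER estimate stays unbiased; only its Monte-Carlo
  variance grows slightly. Reference problem sizes (2562-vertex icosphere,
  188 controls, 200 recovery replicates, 50 power runs) keep the full
  validation suite under a minute.
* Template-to-subject registration is out of scope by design: the lesion-fill
  module verifies lattice agreement and refuses misaligned inputs rather than
  resampling. Optional median-match intensity blending (off by default)
  guards against seam artifacts when template intensities are miscalibrated.

## Known limitations

* **Cluster means are selection-biased.** Reporting the mean observed-minus-
  predicted thickness over a *significant cluster* conditions on vertices
  exceeding the cluster-forming threshold, inflating the reported effect by
  roughly `σ·φ(u)/Φ(u)` with `u = (δ − t·σ)/σ` — about +0.10 mm for a
  0.72 mm effect at σ = 0.2 mm. Simulations here recover ≈ 0.81 mm for an
  injected 0.72 mm. Any cluster-mean report, on real data as in simulation,
  carries this winner's curse; the package reports the quantity as defined
  and documents the bias rather than correcting it post hoc.
* The plain studentized ratio ignores prediction variance (see above);
  at n = 188 the effect on FWER is a fraction of a percentage point.
* Out-of-scope by design: surface extraction and registration, scanner
  harmonization, robust/nonlinear normative models, non-stationary
  smoothness, permutation or FDR alternatives to RFT.
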