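# Methods

## Measurement model

A storage-phosphor plate integrates dose over each exposure window. For a
well with irreversible tracer trapping, the decay-corrected trapped
amount grows linearly, T(τ) = k·τ, where k is the uptake (trapping) rate
in Δ nGy/pixel/min per minute of incubation. The physical signal decays
with the nuclide, so the dose deposited per pixel over a window [t, t+Δ]
is

    dose = m·e^(−μ·h) · I0(t, Δ) + k · I1(t, Δ) + b·Δ,

with m the medium dose rate at the reference time (everything in the well
is ¹⁸F-labelled medium plus trapped tracer), μ the tissue attenuation
coefficient, h the tissue thickness (the medium signal passes through the
tissue to reach the plate; attenuation of the thin trapped layer itself
is neglected), b an optional non-decaying instrument background (default
0), and I0, I1 the window integrals of e^(−λτ) and τ·e^(−λτ).

Decay correction multiplies the window value by
λΔ / (e^(−λ(t−t₀)) (1 − e^(−λΔ))). Applied to the model above, the
corrected per-minute value is exactly k·(t + Δ/2 − c) + m·e^(−μh)·g(λΔ),
where c and g are constants shared by all frames of equal duration.
Hence:

- the corrected series is exactly linear in the frame midpoint, and the
  OLS slope equals k with no bias from the decay-weighted time stamp
  (the constant shift c moves only the intercept) — this is why the
  regression abscissa is the frame midpoint;
- the medium background adds a constant offset, not a slope, so no
  background subtraction is needed for rate estimation (an option
  exists for sensitivity checks by constructing series manually);
- without correction the series bends downward (product of a linear
  ramp with e^(−λt)), which the tests verify as a curvature sign check.

A constant *non-decaying* background would, after correction, grow like
e^(λt) (about 10× over 405 min) and destroy this linearity; that is why
the simulator's in-well background is modelled as decaying medium
activity proportional to the well's MBq rather than as a fixed dose rate.

## Plate response

PSL = offset + decade·(log₁₀(dose/scale) + log₁₀ ratio) with constants
8770 nGy / 1535 PSL / 1024 PSL per decade / ratio 1.25; "log" in the
printed formula is base 10 (the /1024 term writes the response in
decades). The scalar pair `psl_to_dose`/`dose_to_psl` is an exact
algebraic inverse (round trip < 1e−9 relative over 1–10⁷ nGy). Image
decoding is the one place a floor matters: the formula maps low doses to
PSL below 1, which a 16-bit image cannot represent, so the simulator
clips rendered PSL to [1, 65535] and `psl_image_to_dose` decodes pixels
at or below the floor (default 1 PSL ≈ 223 nGy nominal) as 0 nGy —
"below detection limit" — rather than as a spurious constant dose.
Simulation parameters are chosen so that tissue wells stay above the
floor (see below); plate fading between exposure and readout is not
modelled.

## Trapping kinetics and scenario parameters

    k = base · A_MBq · viability · modifier / (1 + glucose/Km)

- **Km = 5.3523 mM**, the bounded least-squares fit of the single-site
  competitive model 100/(1+g/Km) to the observed relative rates
  89/73/44/39/23 % at 1/2/5/10/20 mM with a no-added-glucose control
  (`fit_km_glucose` reproduces it; maximum deviation 7.7 points).
- **base = 10.41 per MBq**, anchored so the reference condition
  (0.04625 MBq, 5 mM glucose, healthy tissue) traps at the observed
  control rate 0.249 Δ nGy/pixel/min.
- Scenario presets: activity titration 0.0115625–0.37 MBq (6 levels,
  n=4); glucose competition control + 1/2/5/10/20 mM (n=4); growth with
  relative cell density 0.45/1.0/1.35 and thickness 60/100/130 µm for
  days 3/6/14 (n=5); chemical insults scaling viability by the observed
  survival 0.21/0.24/0.12/0.14 (n=4); hypothermia/hypoxia as metabolic
  modifiers 0.34/2.35 with viability 1 (n=4). Cell-viability ground
  truth is carried directly on the condition (destructive-assay
  chemistry is not modelled).

## Noise model and its calibration

Two stochastic layers, both seeded through `PhantomSpec.seed`:

- **Poisson counting noise** on a latent photon count proportional to the
  integrated dose before plate-log rendering; `noise_scale` = 1
  photon/nGy by default, giving percent-level pixel noise that averages
  to <0.1% over a ~450-pixel ROI.
- **Between-replicate biological scatter**: a mean-preserving lognormal
  multiplier on each well's trapping rate, `replicate_cv = 0.15`.

The replicate scatter, not the counting noise, is what reproduces the
5–13% CV(SEM) observed across n=4 replicate tissues: ROI-averaged
counting noise at any count level compatible with the plate floor is far
too small, and pushing Poisson sparseness high enough to matter would
clamp most pixels at the floor and bias the series. With cv = 0.15 the
expected CV(SEM) of an n=4 group is ≈ 0.15·c₄/2 ≈ 6.9%, mid-band.

Other defaults: `medium_dose_rate_per_MBq = 6000` nGy/pixel/min per MBq
(keeps the faintest titration well above the plate floor in the last
frame while the brightest stays far from 16-bit overflow),
`mu_per_um = 0.0025`/µm (no published value exists; the simulator's μ is
the oracle for thickness recovery; 100 µm of tissue attenuates ~22%),
pixel size 500 µm, 12-pixel well radius (12 mm discs), 7 frames of
45 min starting every 60 min (the 60-min-exchange convention; frame
count is configurable where a 45-min spacing reading is preferred).

What the simulator does **not** emulate — and therefore what passing
tests do not establish about real data: optical light scatter and plate
fading, partial-volume effects at ROI edges (masks are binary discs),
within-tissue glucose/oxygen gradients, frame-to-frame misalignment from
plate exchanges, and any systematic error of the manufacturer's
calibration formula itself.

## Statistics

The Steel many-to-one test uses Wilcoxon rank sums with midranks; each
treatment's adjusted p is the probability, under joint permutation of
all group labels, that the **maximum** standardized statistic across
treatments reaches the observed one. Arrangements are enumerated exactly
when their number is ≤ `max_exact` (10⁴ by default), otherwise seeded
Monte Carlo with ≥ 10⁴ draws and the add-one estimator. This replaces the
classical equicorrelated-normal critical values with an exact reference
distribution at the study's n = 4–5 group sizes; with one treatment it
reduces exactly to the two-sample Wilcoxon test (verified against an
independent exact implementation). Two-sided is the default alternative.

Small-sample discreteness is intrinsic and worth knowing: with four
observations per group, the most extreme possible outcome has a
family-wise tail probability of ≈ 0.056 for two treatments and ≈ 0.11
for five (two-sided), so no outcome can reach p ≤ 0.05 and the realized
family-wise error rate at α = 0.05 is ~0 rather than ≈ α. The result
object reports `min_attainable_adjusted_p` so users can see when they
are in this regime. All-tied comparisons yield statistic 0 and p = 1
with a warning.

Spearman correlation uses midranks (constant inputs are undefined and
returned as NaN with a warning, not as 0); CV = 100·(SEM or SD)/mean
with the sample SD (ddof = 1), SEM = SD/√n.

## Dosimetry

Atoms N = A·T½/ln2; expected last-nuclide time T½·log₂N (the
deterministic E[N(t)] = 1 definition, not a stochastic first-passage
time); cumulated activity Ã = A₀/(λ_phys + λ_bio); absorbed dose
D = Ã·E/m with E the configured energy absorbed per decay (a product of
mean emitted energy and absorbed fraction — no particle transport);
effective dose D·w_R·w_T with defaults w_R = 1, w_T = 0.01. The default
E = 1.5e−16 J (~0.9 keV per decay, ~0.4% of the mean β⁺ energy) and
m = 1.1e−5 kg (12 mm × 100 µm disc) give the tentative 6 mGy / 0.06 mSv
figures for 0.04625 MBq. The ¹⁸F half-life default is 109.77 min and
configurable. Note one source inconsistency carried deliberately: the
activity 0.0425 MBq is sometimes quoted alongside 4.40×10⁸ atoms, but
that atom count corresponds to 0.04625 MBq (0.0425 MBq gives 4.04×10⁸);
the package computes the count from 0.04625 MBq.

## Numerical choices and degenerate inputs

- Decay-correction uses `expm1` for small λΔ stability; factor → 1 as
  Δ → 0 at the reference time.
- OLS via `scipy.stats.linregress` (cross-checked against statsmodels
  OLS); a constant series returns slope 0 exactly; fewer than 2 frames
  or zero time variance raise errors.
- Thickness mapping: tissue ≥ background → 0 µm; background at/below the
  plate floor → NaN (undefined), never an exception.
- Exposure schedules validate strictly increasing, non-overlapping
  frames; stacks validate frame count against the schedule.
- Rendered images are quantized to integer PSL; the resulting relative
  dose error (< 0.12%) is far below all stated tolerances.
- Test problem sizes (single plates of 24–200 wells, 10–20 replicate
  simulated experiments for the stochastic design checks, 2000 null
  replicates for the Steel calibration) were chosen as the smallest
  designs whose Monte-Carlo error is well inside the corresponding
  tolerance bands.

## Known limitations

- The simulator's realism choices (replicate CV, medium background
  level, attenuation coefficient) are calibrated to summary statistics,
  not to deposited raw images — none exist publicly for this experiment.
- The MIRD reduction ignores source-target geometry beyond the single
  configured absorbed-fraction product.
- Automatic ROI segmentation and inter-frame registration are out of
  scope; masks are caller-provided, as in manual ROI workflows.
- The Steel test's permutation reference assumes exchangeability across
  all groups under the null (identical distributions), the standard
  rank-test assumption.
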