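# bioradiq

Quantification of **dynamic [¹⁸F]FDG bioradiography**: repeated-exposure
autoradiography of living tissue with a PET tracer, read out on
storage-phosphor (radioluminography) plates. The intended users are
researchers evaluating cell viability and metabolic activity of cultured
tissues (e.g. reconstructed human epidermal models for transplantation
quality control) from multiwell imaging-chamber experiments.

## What it computes

Starting from photostimulated-luminescence (PSL) images of 45-min plate
exposures exchanged every 60 min over 405 min of incubation:

1. **Plate response.** PSL is logarithmic in dose; readings are converted
   to 80 kV X-ray-equivalent dose with the manufacturer's formula
   `nGy = 8770 · 10^((PSL − 1535)/1024 − log₁₀ 1.25)` (exact inverse
   available for simulation).
2. **Decay correction.** Each exposure window [t, t+Δ] is rescaled to its
   reference-time value with
   `f = λΔ / (e^(−λ(t−t₀)) (1 − e^(−λΔ)))`, λ = ln2/109.77 min⁻¹ for ¹⁸F.
3. **Uptake rate.** [¹⁸F]FDG is trapped irreversibly, so decay-corrected
   per-pixel dose rate grows linearly with incubation time; the uptake
   rate (Δ nGy/pixel/min) is the OLS slope versus frame midpoints —
   statsmodels-style via `UptakeModel(...).fit()` → `UptakeResults`
   (`summary()`, `params`, `bse`, `plot_fit()`).
4. **Group comparison.** Steel many-to-one rank test (treatments vs a
   shared control) with family-wise control by the permutation
   distribution of the maximum standardized rank statistic (exact for
   small groups, seeded Monte Carlo otherwise); Spearman rank correlation
   and the coefficient of variation.
5. **Dosimetry.** Atom counts from activity (N = A·T½/ln2), expected
   last-nuclide time (T½·log₂N), cumulated activity, and the reduced MIRD
   chain `D = Ã·E/m`, `E_eff = D·w_R·w_T`.
6. **Synthetic experiments.** A ground-truthed simulator of the multiwell
   experiment (trapping kinetics ∝ activity × viability × modifier /
   (1 + glucose/Km), physical decay inside and between frames, Poisson
   noise, replicate scatter, plate-log rendering, tissue attenuation of
   the medium background) with presets for the activity titration,
   glucose competition, growth, chemical-insult and
   hypothermia/hypoxia designs.

## Worked example

Simulate the hypothermia/hypoxia experiment (4 replicates per group) and
quantify it:

```python
from bioradiq.simulate import scenario, simulate_stack
from bioradiq.quantify import UptakeModel, relative_to_control
from bioradiq.stats import GroupData, steel_test

phantom, design = scenario("fig6_hypo", seed=1)
sim = simulate_stack(phantom, design=design)
results = UptakeModel.from_stack(sim.stack, sim.roi_mask).fit()
df = results.to_frame().merge(sim.design, on="roi_id")
groups = {g: s.uptake_rate_dnGy_per_pixel_per_min.to_numpy()
          for g, s in df.groupby("group", sort=False)}
print(relative_to_control(groups, "control").to_string(index=False))
```

prints

```
  condition  n  percent_of_control  sem_percent
    control  4          100.000000     9.295860
hypothermia  4           35.503341     2.793449
    hypoxia  4          242.461997    16.475995
```

i.e. the fitted uptake rates recover the simulated metabolic effects:
hypothermia suppresses uptake to ~35% of control and hypoxia raises it to
~240% (enhanced glycolysis) while ground-truth viability stays 1.0.
Individual well fits (`results.summary()`) show R² ≥ 0.999 — the
decay-corrected series are linear, as expected for irreversible trapping.
The Steel test on these groups reports z = ±2.31 with adjusted
p = 0.056 for both treatments: with n = 4 per group the rank statistics
are so discrete that 0.056 is the smallest attainable two-sided
family-wise p (exposed as `SteelResult.min_attainable_adjusted_p`).

The dosimetry chain, with the default 0.04625 MBq medium activity:

```python
from bioradiq.decay import estimate_dose
est = estimate_dose()   # absorbed 5.993 mGy -> effective 0.0599 mSv
```

well below the 1 mSv/year public dose limit.

The command line mirrors the library: `bioradiq simulate|quantify|stats|
dose|run --config config.yaml --out-dir out` (see `bioradiq --help`).
Outputs are tidy CSV/JSON with units in every column name and the config
hash and seed in every header; identical config + seed reproduces
byte-identical files.

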