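"""ROI series extraction, uptake-rate fitting, attenuation thickness."""

import math

import numpy as np
import pandas as pd
import pytest

from bioradiq.decay import F18, decay_correction_factor
from bioradiq.plate import dose_to_psl
from bioradiq.quantify import (
    ExposureSchedule,
    ImageStack,
    UptakeModel,
    UptakeSeries,
    attenuation_thickness_map,
    extract_uptake_series,
    fit_uptake_rate,
    relative_to_control,
)
from bioradiq.simulate import PhantomSpec, Well, WellCondition, simulate_stack, transmission_pair

from conftest import fit_rates_frame


def _stack_from_doses(doses, schedule, calib):
    """Encode per-frame uniform integrated doses (nGy/pixel) as a PSL stack."""
    frames = np.stack(
        [np.full((4, 4), dose_to_psl(d, calib)) if d > 0 else np.ones((4, 4)) for d in doses]
    )
    return ImageStack(frames=frames, schedule=schedule)


class TestScheduleAndStack:
    def test_regular_schedule_matches_default_protocol(self, default_schedule):
        assert len(default_schedule) == 7
        assert default_schedule.starts[-1] == 360.0
        assert np.all(default_schedule.durations == 45.0)
        assert default_schedule.midpoints[0] == 22.5

    def test_frame_count_must_match_schedule(self, default_schedule):
        with pytest.raises(ValueError, match="does not match schedule"):
            ImageStack(frames=np.zeros((3, 4, 4)), schedule=default_schedule)

    def test_decreasing_starts_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ExposureSchedule(((60.0, 45.0), (0.0, 45.0)))


class TestExtraction:
    def test_mask_shape_mismatch_and_missing_labels(self, noiseless_sim):
        with pytest.raises(ValueError, match="mask shape"):
            extract_uptake_series(noiseless_sim.stack, np.zeros((2, 2)))
        with pytest.raises(ValueError, match="no non-zero labels"):
            extract_uptake_series(noiseless_sim.stack, np.zeros(noiseless_sim.roi_mask.shape))

    def test_zero_background_roi_gives_all_zero_series(self, default_schedule, calib):
        frames = np.ones((7, 4, 4))  # everything at the plate floor
        stack = ImageStack(frames=frames, schedule=default_schedule)
        series = extract_uptake_series(stack, np.ones((4, 4), dtype=int), calib)
        assert np.all(series[1].uptake == 0.0)

    def test_removing_decay_correction_scales_by_frame_decay(self, default_schedule, calib):
        # constant physical dose per frame: after correction, frame values
        # differ by exactly exp(lambda * start); removing the correction on a
        # late frame therefore lowers it by exp(-lambda * start)
        doses = 1000.0 * np.ones(7)
        stack = _stack_from_doses(doses, default_schedule, calib)
        mask = np.ones((4, 4), dtype=int)
        corrected = extract_uptake_series(stack, mask, calib)[1].uptake
        lam = F18.decay_constant_per_min
        gap = default_schedule.starts[3] - default_schedule.starts[0]
        assert corrected[3] / corrected[0] == pytest.approx(math.exp(lam * gap), rel=1e-9)
        factors = np.array([decay_correction_factor(s, d) for s, d in default_schedule.frames])
        assert np.all(corrected / factors == pytest.approx(corrected[0] / factors[0], rel=1e-9))

    def test_uptake_invariant_to_roi_size(self):
        # per-pixel normalization: a concentric smaller ROI reads the same value
        cond = WellCondition()
        phantom = PhantomSpec(
            wells=(Well((18, 18), 12, cond, 1),), image_shape=(36, 36), seed=2, noise_scale=None, replicate_cv=0.0
        )
        sim = simulate_stack(phantom)
        full = extract_uptake_series(sim.stack, sim.roi_mask)[1].uptake
        rr, cc = np.ogrid[:36, :36]
        small = ((rr - 18) ** 2 + (cc - 18) ** 2 <= 6**2).astype(int)
        inner = extract_uptake_series(sim.stack, small)[1].uptake
        assert inner == pytest.approx(full, rel=5e-3)

    def test_corrected_series_linear_uncorrected_concave(self):
        # trap-only phantom (no medium background): decay correction removes
        # all curvature, the raw series bends down as the tracer decays
        phantom = PhantomSpec(
            wells=(Well((18, 18), 12, WellCondition(glucose_mM=0.0), 1),),
            image_shape=(36, 36),
            seed=2,
            noise_scale=None,
            replicate_cv=0.0,
            medium_dose_rate_per_MBq=0.0,
        )
        sim = simulate_stack(phantom)
        sched = sim.stack.schedule
        factors = np.array([decay_correction_factor(s, d) for s, d in sched.frames])
        series = extract_uptake_series(sim.stack, sim.roi_mask)[1]
        t = sched.midpoints
        corr_quad = np.polyfit(t, series.uptake, 2)[0]
        uncorr_quad = np.polyfit(t, series.uptake / factors, 2)[0]
        scale = series.uptake.mean() / t.mean() ** 2
        assert abs(corr_quad) < 0.02 * scale
        assert uncorr_quad < -0.1 * scale


class TestRateFit:
    def test_exact_line_recovered(self):
        t = np.array([22.5, 82.5, 142.5, 202.5, 262.5, 322.5, 382.5])
        series = UptakeSeries(1, t, 0.002 * t + 0.1)
        fit = fit_uptake_rate(series)
        assert fit.slope == pytest.approx(0.002, rel=1e-12)
        assert fit.intercept == pytest.approx(0.1, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_has_zero_slope(self):
        fit = fit_uptake_rate(UptakeSeries(1, np.array([0.0, 60.0, 120.0]), np.full(3, 5.0)))
        assert fit.slope == 0.0

    def test_too_few_frames_and_degenerate_times(self):
        with pytest.raises(ValueError, match="at least 2 frames"):
            fit_uptake_rate(UptakeSeries(1, np.array([10.0]), np.array([1.0])))
        with pytest.raises(ValueError, match="zero variance"):
            fit_uptake_rate(
                UptakeSeries(1, np.array([10.0, 10.0]), np.array([1.0, 2.0]))
            )

    def test_slope_equivariant_under_dose_scaling(self):
        t = np.array([22.5, 82.5, 142.5, 202.5])
        y = np.array([1.0, 2.2, 2.9, 4.1])
        s1 = fit_uptake_rate(UptakeSeries(1, t, y)).slope
        s2 = fit_uptake_rate(UptakeSeries(1, t, 3.5 * y)).slope
        assert s2 == pytest.approx(3.5 * s1, rel=1e-12)

    def test_model_results_agree_with_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        t = np.array([22.5, 82.5, 142.5, 202.5, 262.5, 322.5, 382.5])
        y = 0.25 * t + 5 + rng.normal(0, 2.0, t.size)
        df = pd.DataFrame({"roi_id": 1, "time_min": t, "uptake_nGy_per_pixel_per_min": y})
        results = UptakeModel.from_dataframe(df).fit()
        ols = sm.OLS(y, sm.add_constant(t)).fit()
        assert results.params[1] == pytest.approx(ols.params[1], rel=1e-10)
        assert results.bse[1] == pytest.approx(ols.bse[1], rel=1e-10)
        assert results.fits[1].r_squared == pytest.approx(ols.rsquared, rel=1e-10)
        assert "Uptake rate" in results.summary()

    def test_end_to_end_recovery_regression(self):
        from scipy.stats import linregress

        from bioradiq.simulate import random_phantom

        df = fit_rates_frame(simulate_stack(random_phantom(60, seed=17)))
        fit = linregress(df.true_rate_dnGy_per_pixel_per_min, df.uptake_rate_dnGy_per_pixel_per_min)
        assert fit.slope == pytest.approx(1.0, abs=0.03)
        assert fit.rvalue**2 > 0.98


class TestAttenuationThickness:
    def test_exact_inversion(self, calib):
        mu = 0.0025
        bg_dose = 10000.0
        bg = np.full((2, 2), dose_to_psl(bg_dose, calib))
        same = attenuation_thickness_map(bg, bg, calib, mu)
        assert same == pytest.approx(np.zeros((2, 2)), abs=1e-9)
        tissue = np.full((2, 2), dose_to_psl(bg_dose * math.exp(-mu * 100), calib))
        t = attenuation_thickness_map(bg, tissue, calib, mu)
        assert t == pytest.approx(np.full((2, 2), 100.0), rel=1e-6)

    def test_brighter_tissue_reports_zero_and_floor_is_nan(self, calib):
        bg = np.array([[dose_to_psl(1000.0, calib), 1.0]])
        tissue = np.array([[dose_to_psl(2000.0, calib), 1.0]])
        t = attenuation_thickness_map(bg, tissue, calib, 0.0025)
        assert t[0, 0] == 0.0  # tissue brighter than background
        assert np.isnan(t[0, 1])  # both at the plate floor: undefined

    def test_simulated_phantom_recovers_100_um(self):
        phantom = PhantomSpec(
            wells=(Well((18, 18), 12, WellCondition(), 1),), image_shape=(36, 36), seed=13
        )
        bg, tissue = transmission_pair(phantom)
        t = attenuation_thickness_map(bg, tissue, mu_per_um=phantom.mu_per_um)
        sim = simulate_stack(phantom)
        median = np.nanmedian(t[sim.roi_mask > 0])
        assert median == pytest.approx(100.0, rel=0.05)


class TestRelativeToControl:
    def test_identities(self):
        out = relative_to_control({"control": [2.0, 2.0], "half": [1.0, 1.0]}, "control")
        out = out.set_index("condition")
        assert out.percent_of_control["control"] == pytest.approx(100.0)
        assert out.percent_of_control["half"] == pytest.approx(50.0)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError, match="control mean is zero"):
            relative_to_control({"control": [0.0, 0.0], "t": [1.0]}, "control")
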