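"""Synthetic experiment generator: kinetics, scenarios, noise, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from bioradiq.quantify import ExposureSchedule, UptakeModel
from bioradiq.simulate import (
    BASE_RATE_PER_MBQ,
    FIG2_ACTIVITIES_MBQ,
    GLUCOSE_RELATIVE_RATES_PCT,
    KM_GLUCOSE_MM,
    PhantomSpec,
    Well,
    WellCondition,
    fit_km_glucose,
    random_phantom,
    scenario,
    simulate_stack,
    trapping_rate,
)

from conftest import fit_rates_frame


class TestTrappingRate:
    def test_glucose_at_km_halves_rate(self):
        zero = trapping_rate(WellCondition(glucose_mM=0.0))
        at_km = trapping_rate(WellCondition(glucose_mM=KM_GLUCOSE_MM))
        assert at_km == pytest.approx(zero / 2, rel=1e-12)

    def test_dead_tissue_has_zero_rate(self):
        assert trapping_rate(WellCondition(viable_cell_density=0.0)) == 0.0

    def test_linear_in_activity_and_cells(self):
        base = trapping_rate(WellCondition())
        assert trapping_rate(WellCondition(fdg_activity_MBq=2 * 0.04625)) == pytest.approx(2 * base)
        assert trapping_rate(WellCondition(viable_cell_density=0.5)) == pytest.approx(base / 2)

    def test_fitted_km_reproduces_frozen_constant(self):
        assert fit_km_glucose() == pytest.approx(KM_GLUCOSE_MM, abs=1e-3)

    def test_fitted_km_predictions_match_published_series(self):
        # competitive model at the fitted Km vs the published percentages
        for g, pct in GLUCOSE_RELATIVE_RATES_PCT.items():
            pred = 100.0 / (1.0 + g / KM_GLUCOSE_MM)
            assert pred == pytest.approx(pct, abs=12.0)

    def test_reference_condition_anchor(self):
        # 0.04625 MBq at 5 mM glucose traps at the published control rate
        assert trapping_rate(WellCondition()) == pytest.approx(
            BASE_RATE_PER_MBQ * 0.04625 / (1 + 5 / KM_GLUCOSE_MM), rel=1e-12
        )


class TestScenarios:
    def test_glucose_scenario_layout(self):
        phantom, design = scenario("fig3_glucose", seed=0)
        assert len(phantom.wells) == 24  # control + 5 glucose levels, 4 replicates
        assert design.groupby("group").size().eq(4).all()
        assert set(design.group) == {"control", "1mM", "2mM", "5mM", "10mM", "20mM"}

    def test_activity_scenario_uses_published_titration(self):
        phantom, design = scenario("fig2_activity", seed=0)
        activities = sorted({w.condition.fdg_activity_MBq for w in phantom.wells})
        assert activities == pytest.approx(list(FIG2_ACTIVITIES_MBQ))

    def test_growth_scenario_has_five_replicates(self):
        _, design = scenario("fig4_growth", seed=0)
        assert design.groupby("group").size().eq(5).all()

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario("fig9_nonexistent", seed=0)

    def test_same_seed_bit_identical_different_seed_differs(self):
        phantom, _ = scenario("fig3_glucose", seed=5, n_replicates=2)
        a = simulate_stack(phantom).stack.frames
        b = simulate_stack(phantom).stack.frames
        assert np.array_equal(a, b)
        phantom2, _ = scenario("fig3_glucose", seed=6, n_replicates=2)
        assert not np.array_equal(a, simulate_stack(phantom2).stack.frames)


class TestPhantomValidation:
    def test_overlapping_wells_rejected(self):
        w = WellCondition()
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(
                wells=(
                    Well((20, 20), 12, w, 1),
                    Well((20, 30), 12, w, 2),
                ),
                image_shape=(64, 64),
            )

    def test_out_of_bounds_well_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            PhantomSpec(wells=(Well((5, 5), 12, WellCondition(), 1),), image_shape=(64, 64))

    def test_overlapping_schedule_frames_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            ExposureSchedule(((0.0, 45.0), (30.0, 45.0)))


class TestSimulatedPhysics:
    def test_noiseless_recovery_within_two_percent(self, noiseless_sim):
        df = fit_rates_frame(noiseless_sim)
        rel = df.uptake_rate_dnGy_per_pixel_per_min / df.true_rate_dnGy_per_pixel_per_min - 1
        assert rel.abs().max() < 0.02
        assert df.r_squared.min() >= 0.999

    def test_zero_activity_well_is_flat_background(self):
        cond = WellCondition(fdg_activity_MBq=0.0)
        phantom = PhantomSpec(wells=(Well((18, 18), 12, cond, 1),), image_shape=(36, 36), seed=3)
        sim = simulate_stack(phantom)
        inside = sim.stack.frames[:, sim.roi_mask > 0]
        # nothing radioactive: every frame sits at the plate floor
        assert np.all(inside == phantom.psl_floor)

    def test_doubling_activity_doubles_recovered_slope(self):
        conds = [
            ("a", WellCondition(fdg_activity_MBq=0.04625)),
            ("2a", WellCondition(fdg_activity_MBq=0.0925)),
        ]
        wells = tuple(
            Well((18, 18 + 36 * i), 12, c, i + 1, group=g) for i, (g, c) in enumerate(conds)
        )
        phantom = PhantomSpec(wells=wells, image_shape=(36, 72), seed=8, replicate_cv=0.0)
        df = fit_rates_frame(simulate_stack(phantom))
        ratio = (
            df.set_index("roi_id").uptake_rate_dnGy_per_pixel_per_min[2]
            / df.set_index("roi_id").uptake_rate_dnGy_per_pixel_per_min[1]
        )
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_slope_estimates_unbiased_under_default_noise(self):
        # 200 random wells: mean fitted/true ratio within 2% of unity
        phantom = random_phantom(200, seed=21)
        df = fit_rates_frame(simulate_stack(phantom))
        ratio = df.uptake_rate_dnGy_per_pixel_per_min / df.true_rate_dnGy_per_pixel_per_min
        assert abs(ratio.mean() - 1) < 0.02

    def test_hypoxia_raises_rate_without_killing_cells(self):
        # metabolic modifier 2.35 vs control while ground-truth viability stays 1
        pcts = []
        for s in range(8):
            phantom, design = scenario("fig6_hypo", seed=300 + s)
            sim = simulate_stack(phantom, design=design)
            df = fit_rates_frame(sim)
            assert (df.viable_cell_density == 1.0).all()
            means = df.groupby("group").uptake_rate_dnGy_per_pixel_per_min.mean()
            pcts.append(100 * means["hypoxia"] / means["control"])
        assert np.mean(pcts) == pytest.approx(235.0, abs=25.0)
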