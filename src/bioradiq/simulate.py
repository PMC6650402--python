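"""Synthetic multiwell [18F]FDG bioradiography experiments.

The generator emulates the imaging-chamber experiment end to end: disc
tissue phantoms in a multiwell geometry, irreversible FDG trapping that is
linear in decay-corrected time and proportional to medium activity, viable
cell density and a metabolic modifier, competitively suppressed by medium
glucose through a single apparent Km; physical 18F decay inside and
between 45-min exposures; Poisson counting noise; between-replicate
biological scatter; and rendering through the plate's saturating
logarithmic response to 16-bit PSL images.

Physical model per pixel inside a well, for an exposure window [t, t+D]
(times in decay-corrected incubation minutes, reference t = 0):

    dose(nGy) = medium * exp(-mu * thickness) * I0(t, D)
                + rate * I1(t, D) + plate_bg * D,

where medium = activity_MBq * medium_dose_rate_per_MBq is the dose rate
from the 0.5 mL labelled medium (attenuated by the overlying tissue),
rate is the well's realized trapping rate, I0 = integral of exp(-lam tau)
and I1 = integral of tau exp(-lam tau) over the window (trapped amount
rate*tau in the decay-corrected domain times physical decay), and
plate_bg is an optional non-decaying instrument background (default 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .decay import F18, NuclideSpec
from .plate import DEFAULT_CALIBRATION, PlateCalibration, dose_to_psl
from .quantify import ExposureSchedule, ImageStack

__all__ = [
    "KM_GLUCOSE_MM",
    "BASE_RATE_PER_MBQ",
    "GLUCOSE_RELATIVE_RATES_PCT",
    "FIG2_ACTIVITIES_MBQ",
    "SCENARIO_NAMES",
    "WellCondition",
    "Well",
    "PhantomSpec",
    "SimulationResult",
    "fit_km_glucose",
    "trapping_rate",
    "simulate_stack",
    "transmission_pair",
    "scenario",
    "random_phantom",
]

#: Published relative uptake rates (percent of the no-added-glucose control)
#: at 1, 2, 5, 10 and 20 mM medium glucose.
GLUCOSE_RELATIVE_RATES_PCT = {1.0: 89.0, 2.0: 73.0, 5.0: 44.0, 10.0: 39.0, 20.0: 23.0}

#: Medium activity titration of the concentration-response experiment (MBq / 0.5 mL).
FIG2_ACTIVITIES_MBQ = (0.0115625, 0.023125, 0.04625, 0.0925, 0.185, 0.37)

#: Apparent competitive Km of medium glucose (mM), least-squares fitted to
#: GLUCOSE_RELATIVE_RATES_PCT with a 0 mM control (see fit_km_glucose).
KM_GLUCOSE_MM = 5.3523

#: Trapping rate per MBq of medium activity at zero glucose, unit viability
#: (dnGy/pixel/min per minute per MBq), anchored so the reference condition
#: (0.04625 MBq, 5 mM glucose, healthy day-6 tissue) traps at the published
#: control uptake rate 0.249 dnGy/pixel/min.
BASE_RATE_PER_MBQ = 0.249 * (1.0 + 5.0 / KM_GLUCOSE_MM) / 0.04625

SCENARIO_NAMES = ("fig2_activity", "fig3_glucose", "fig4_growth", "fig5_insult", "fig6_hypo")


def fit_km_glucose(
    relative_rates_pct: "dict[float, float]" = GLUCOSE_RELATIVE_RATES_PCT,
    bounds: "tuple[float, float]" = (0.5, 20.0),
) -> float:
    """Least-squares apparent Km (mM) of single-site competitive inhibition.

    Fits percent-of-control = 100 / (1 + glucose/Km) to the observed
    series; the control carries no added glucose.
    """
    g = np.array(list(relative_rates_pct), dtype=float)
    p = np.array(list(relative_rates_pct.values()), dtype=float) / 100.0
    res = minimize_scalar(
        lambda k: float(np.sum((1.0 / (1.0 + g / k) - p) ** 2)),
        bounds=bounds,
        method="bounded",
    )
    return float(res.x)


@dataclass(frozen=True)
class WellCondition:
    """Ground-truth experimental condition of one well."""

    fdg_activity_MBq: float = 0.04625
    glucose_mM: float = 5.0
    viable_cell_density: float = 1.0
    metabolic_modifier: float = 1.0
    tissue_thickness_um: float = 100.0
    km_glucose_mM: float = KM_GLUCOSE_MM

    def __post_init__(self) -> None:
        for name in (
            "fdg_activity_MBq",
            "glucose_mM",
            "viable_cell_density",
            "metabolic_modifier",
            "tissue_thickness_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"WellCondition.{name} must be >= 0")
        if self.km_glucose_mM <= 0:
            raise ValueError("WellCondition.km_glucose_mM must be > 0")


def trapping_rate(cond: WellCondition, base_rate_per_MBq: float = BASE_RATE_PER_MBQ) -> float:
    """True trapping rate (dnGy/pixel/min per min) implied by a condition.

    Linear in medium activity and viable cell density, scaled by the
    metabolic modifier, competitively suppressed by glucose:
    1 / (1 + glucose / Km).
    """
    return (
        base_rate_per_MBq
        * cond.fdg_activity_MBq
        * cond.viable_cell_density
        * cond.metabolic_modifier
        / (1.0 + cond.glucose_mM / cond.km_glucose_mM)
    )


@dataclass(frozen=True)
class Well:
    center: "tuple[float, float]"  # (row, col) pixels
    radius_px: float
    condition: WellCondition
    label: int
    group: str = ""


@dataclass(frozen=True)
class PhantomSpec:
    """Simulation parameters for one plate."""

    wells: "tuple[Well, ...]"
    image_shape: "tuple[int, int]" = (128, 128)
    pixel_size_um: float = 500.0
    medium_dose_rate_per_MBq: float = 6000.0  # nGy/pixel/min per MBq in the well
    plate_background_rate: float = 0.0  # non-decaying instrument background, nGy/pixel/min
    mu_per_um: float = 0.0025  # radiation attenuation coefficient of tissue, per um
    noise_scale: "float | None" = 1.0  # latent photons per nGy; None = noiseless
    replicate_cv: float = 0.15  # between-well biological CV of the trapping rate
    psl_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        if not self.wells:
            raise ValueError("PhantomSpec requires at least one well")
        h, w = self.image_shape
        labels = set()
        for well in self.wells:
            r, c = well.center
            if not (well.radius_px <= r <= h - well.radius_px and well.radius_px <= c <= w - well.radius_px):
                raise ValueError(f"well {well.label} does not fit inside image shape {self.image_shape}")
            if well.label in labels or well.label == 0:
                raise ValueError(f"well labels must be unique and non-zero, got {well.label}")
            labels.add(well.label)
        for i, a in enumerate(self.wells):
            for b in self.wells[i + 1 :]:
                dist = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if dist < a.radius_px + b.radius_px:
                    raise ValueError(f"wells {a.label} and {b.label} overlap")
        if self.noise_scale is not None and self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive or None")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")


@dataclass
class SimulationResult:
    """Simulated stack plus everything downstream tests need as ground truth."""

    stack: ImageStack
    roi_mask: np.ndarray
    truth: pd.DataFrame  # one row per well: realized rate, viability, thickness...
    design: pd.DataFrame
    phantom: PhantomSpec


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _window_integrals(start: float, duration: float, lam: float) -> "tuple[float, float]":
    """(I0, I1) = integrals of exp(-lam t) and t exp(-lam t) over the window."""
    t0, t1 = start, start + duration
    e0, e1 = math.exp(-lam * t0), math.exp(-lam * t1)
    i0 = (e0 - e1) / lam
    i1 = (t0 / lam + 1.0 / lam**2) * e0 - (t1 / lam + 1.0 / lam**2) * e1
    return i0, i1


def _render_frame(dose: np.ndarray, calib: PlateCalibration, psl_floor: float, noise_scale, rng) -> np.ndarray:
    if noise_scale is not None:
        dose = rng.poisson(dose * noise_scale).astype(float) / noise_scale
    psl = np.full(dose.shape, psl_floor)
    positive = dose > 0
    psl[positive] = dose_to_psl(dose[positive], calib)
    return np.clip(np.rint(psl), psl_floor, 65535).astype(np.uint16)


def _realized_rates(phantom: PhantomSpec, rng) -> np.ndarray:
    base = np.array([trapping_rate(w.condition) for w in phantom.wells])
    if phantom.replicate_cv > 0:
        sigma = math.sqrt(math.log1p(phantom.replicate_cv**2))
        base = base * rng.lognormal(-(sigma**2) / 2.0, sigma, size=base.size)
    return base


def simulate_stack(
    phantom: PhantomSpec,
    schedule: ExposureSchedule | None = None,
    calib: PlateCalibration = DEFAULT_CALIBRATION,
    nuclide: NuclideSpec = F18,
    design: pd.DataFrame | None = None,
) -> SimulationResult:
    """Simulate the exposure series of one plate.

    Deterministic given ``phantom.seed``: the same spec reproduces
    bit-identical stacks.
    """
    if schedule is None:
        schedule = ExposureSchedule.regular()
    rng = np.random.default_rng(phantom.seed)
    lam = nuclide.decay_constant_per_min
    shape = phantom.image_shape

    rates = _realized_rates(phantom, rng)
    medium_map = np.zeros(shape)
    trap_map = np.zeros(shape)
    mask = np.zeros(shape, dtype=np.uint16)
    rows = []
    for well, rate in zip(phantom.wells, rates):
        disc = _disc_mask(shape, well.center, well.radius_px)
        cond = well.condition
        attn = math.exp(-phantom.mu_per_um * cond.tissue_thickness_um)
        medium_map[disc] = cond.fdg_activity_MBq * phantom.medium_dose_rate_per_MBq * attn
        trap_map[disc] = rate
        mask[disc] = well.label
        rows.append(
            {
                "roi_id": well.label,
                "group": well.group,
                "true_rate_dnGy_per_pixel_per_min": rate,
                "viable_cell_density": cond.viable_cell_density,
                "tissue_thickness_um": cond.tissue_thickness_um,
                "fdg_activity_MBq": cond.fdg_activity_MBq,
                "glucose_mM": cond.glucose_mM,
                "metabolic_modifier": cond.metabolic_modifier,
            }
        )

    frames = np.empty((len(schedule), *shape), dtype=np.uint16)
    for k, (start, dur) in enumerate(schedule.frames):
        i0, i1 = _window_integrals(start, dur, lam)
        dose = medium_map * i0 + trap_map * i1 + phantom.plate_background_rate * dur
        frames[k] = _render_frame(dose, calib, phantom.psl_floor, phantom.noise_scale, rng)

    stack = ImageStack(frames=frames, schedule=schedule, pixel_size_um=phantom.pixel_size_um)
    truth = pd.DataFrame(rows)
    if design is None:
        design = truth[["roi_id", "group"]].copy()
    return SimulationResult(stack=stack, roi_mask=mask, truth=truth, design=design, phantom=phantom)


def transmission_pair(
    phantom: PhantomSpec,
    exposure_min: float = 45.0,
    calib: PlateCalibration = DEFAULT_CALIBRATION,
    nuclide: NuclideSpec = F18,
) -> "tuple[np.ndarray, np.ndarray]":
    """(background, time-zero tissue) PSL images for attenuation mapping.

    Both are single exposures over [0, exposure_min] of the same wells:
    the background image without tissue, the tissue image with tissue
    present but no uptake (dead-tracer transmission geometry).  Decay is
    common to both and cancels in the dose ratio.
    """
    no_tissue = replace(
        phantom,
        wells=tuple(
            replace(w, condition=replace(w.condition, tissue_thickness_um=0.0, viable_cell_density=0.0))
            for w in phantom.wells
        ),
    )
    no_uptake = replace(
        phantom,
        seed=phantom.seed + 1,
        wells=tuple(
            replace(w, condition=replace(w.condition, viable_cell_density=0.0)) for w in phantom.wells
        ),
    )
    sched = ExposureSchedule(((0.0, exposure_min),))
    bg = simulate_stack(no_tissue, sched, calib, nuclide).stack.frames[0]
    ti = simulate_stack(no_uptake, sched, calib, nuclide).stack.frames[0]
    return bg, ti


def _grid_phantom(
    conditions: "list[tuple[str, WellCondition]]",
    n_replicates: int,
    seed: int,
    cell_px: int = 36,
    radius_px: float = 12.0,
    **phantom_kwargs,
) -> "tuple[PhantomSpec, pd.DataFrame]":
    """Lay out conditions in columns and replicates in rows."""
    n_cond = len(conditions)
    shape = (n_replicates * cell_px, n_cond * cell_px)
    wells = []
    rows = []
    label = 0
    for j, (group, cond) in enumerate(conditions):
        for i in range(n_replicates):
            label += 1
            center = (cell_px * (i + 0.5), cell_px * (j + 0.5))
            wells.append(Well(center=center, radius_px=radius_px, condition=cond, label=label, group=group))
            rows.append({"roi_id": label, "group": group, "replicate": i + 1})
    phantom = PhantomSpec(wells=tuple(wells), image_shape=shape, seed=seed, **phantom_kwargs)
    return phantom, pd.DataFrame(rows)


def scenario(name: str, seed: int = 0, n_replicates: int | None = None, **phantom_kwargs):
    """Preset phantom + design table for one of the study's experiments.

    fig2_activity : medium activity titration (6 levels, 5 mM glucose).
    fig3_glucose  : glucose competition (no-added-glucose control + 5 levels).
    fig4_growth   : culture days 3/6/14; cell density and thickness grow.
    fig5_insult   : hazardous-chemical insults scaling viability.
    fig6_hypo     : hypothermia (modifier 0.34) and hypoxia (2.35),
                    viability preserved.
    """
    control = WellCondition()
    if name == "fig2_activity":
        conditions = [
            (f"{a:g}MBq", WellCondition(fdg_activity_MBq=a)) for a in FIG2_ACTIVITIES_MBQ
        ]
        n = n_replicates or 4
    elif name == "fig3_glucose":
        conditions = [("control", WellCondition(glucose_mM=0.0))] + [
            (f"{g:g}mM", WellCondition(glucose_mM=g)) for g in GLUCOSE_RELATIVE_RATES_PCT
        ]
        n = n_replicates or 4
    elif name == "fig4_growth":
        growth = {"day3": (0.45, 60.0), "day6": (1.0, 100.0), "day14": (1.35, 130.0)}
        conditions = [
            (day, WellCondition(viable_cell_density=v, tissue_thickness_um=t))
            for day, (v, t) in growth.items()
        ]
        n = n_replicates or 5
    elif name == "fig5_insult":
        survival = {
            "sulfuric_acid": 0.21,
            "hydrochloric_acid": 0.24,
            "octanoic_acid": 0.12,
            "potassium_hydroxide": 0.14,
        }
        conditions = [("control", control)] + [
            (chem, WellCondition(viable_cell_density=s)) for chem, s in survival.items()
        ]
        n = n_replicates or 4
    elif name == "fig6_hypo":
        conditions = [
            ("control", control),
            ("hypothermia", WellCondition(metabolic_modifier=0.34)),
            ("hypoxia", WellCondition(metabolic_modifier=2.35)),
        ]
        n = n_replicates or 4
    else:
        raise ValueError(f"unknown scenario {name!r}; choose one of {SCENARIO_NAMES}")
    return _grid_phantom(conditions, n, seed, **phantom_kwargs)


def random_phantom(
    n_wells: int,
    seed: int,
    activity_range: "tuple[float, float]" = (0.023125, 0.37),
    glucose_range: "tuple[float, float]" = (0.0, 20.0),
    viability_range: "tuple[float, float]" = (0.3, 1.0),
    modifier_range: "tuple[float, float]" = (0.5, 2.0),
    **phantom_kwargs,
) -> PhantomSpec:
    """Phantom with wells drawn uniformly from plausible condition ranges."""
    rng = np.random.default_rng(seed)
    conditions = [
        (
            f"w{i}",
            WellCondition(
                fdg_activity_MBq=rng.uniform(*activity_range),
                glucose_mM=rng.uniform(*glucose_range),
                viable_cell_density=rng.uniform(*viability_range),
                metabolic_modifier=rng.uniform(*modifier_range),
            ),
        )
        for i in range(n_wells)
    ]
    side = math.ceil(math.sqrt(n_wells))
    phantom, _ = _grid_phantom(conditions[: side * side][:n_wells], 1, seed, **phantom_kwargs)
    # _grid_phantom lays out one row per replicate; re-grid into a square instead.
    cell = 36
    wells = []
    for k, well in enumerate(phantom.wells):
        i, j = divmod(k, side)
        wells.append(replace(well, center=(cell * (i + 0.5), cell * (j + 0.5))))
    return replace(phantom, wells=tuple(wells), image_shape=(side * cell, side * cell))
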