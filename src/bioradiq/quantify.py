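"""ROI quantification: PSL stacks -> decay-corrected uptake series -> uptake rates.

The measurement model follows irreversible tracer trapping: after decay
correction the per-pixel dose rate in a tissue ROI grows linearly with
incubation time, and the uptake rate (delta nGy/pixel/min per minute of
incubation) is the ordinary-least-squares slope of decay-corrected uptake
versus frame midpoint time.  Decay correction makes the corrected frame
value the window-average trapped amount, so the frame midpoint is the
natural abscissa (all frames share the same duration, so the small
decay-weighted shift of the effective time stamp is a constant that moves
the intercept, never the slope).

`UptakeModel` / `UptakeResults` wrap this estimation statsmodels-style:
build the model from an image stack + ROI label mask (or from a tidy
DataFrame of uptake series), call ``fit()``, and read per-ROI slopes,
standard errors and R^2 off the results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decay import F18, NuclideSpec, decay_correction_factor
from .plate import DEFAULT_CALIBRATION, PlateCalibration, psl_image_to_dose

__all__ = [
    "ExposureSchedule",
    "ImageStack",
    "UptakeSeries",
    "UptakeRateResult",
    "extract_uptake_series",
    "fit_uptake_rate",
    "UptakeModel",
    "UptakeResults",
    "attenuation_thickness_map",
    "relative_to_control",
]


@dataclass(frozen=True)
class ExposureSchedule:
    """Ordered, non-overlapping exposure windows (start_min, duration_min)."""

    frames: tuple

    def __post_init__(self) -> None:
        frames = tuple((float(s), float(d)) for s, d in self.frames)
        object.__setattr__(self, "frames", frames)
        if not frames:
            raise ValueError("schedule must contain at least one frame")
        prev_end = -math.inf
        prev_start = -math.inf
        for start, dur in frames:
            if dur <= 0:
                raise ValueError(f"frame duration must be > 0, got {dur}")
            if start <= prev_start:
                raise ValueError("frame starts must be strictly increasing")
            if start < prev_end:
                raise ValueError(
                    f"frame starting at {start} min overlaps the previous frame ending at {prev_end} min"
                )
            prev_start, prev_end = start, start + dur

    @classmethod
    def regular(
        cls,
        n_frames: int = 7,
        interval_min: float = 60.0,
        duration_min: float = 45.0,
        start_min: float = 0.0,
    ) -> "ExposureSchedule":
        """The experiment's default: 45-min exposures, plate exchanged every 60 min."""
        return cls(tuple((start_min + i * interval_min, duration_min) for i in range(n_frames)))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.frames])

    @property
    def durations(self) -> np.ndarray:
        return np.array([d for _, d in self.frames])

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + self.durations / 2.0


@dataclass
class ImageStack:
    """Per-frame 2-D PSL arrays plus their exposure schedule."""

    frames: np.ndarray
    schedule: ExposureSchedule
    pixel_size_um: float = 500.0
    calibration_id: str = "default"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be a (n_frames, H, W) array, got shape {self.frames.shape}")
        if self.frames.shape[0] != len(self.schedule):
            raise ValueError(
                f"frame count {self.frames.shape[0]} does not match schedule length {len(self.schedule)}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self):
        return self.frames.shape[1:]


@dataclass(frozen=True)
class UptakeSeries:
    """Decay-corrected per-ROI uptake (nGy/pixel/min) per frame."""

    roi_id: int
    times_min: np.ndarray
    uptake: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        u = np.asarray(self.uptake, dtype=float)
        if t.shape != u.shape or t.ndim != 1:
            raise ValueError("times_min and uptake must be 1-D arrays of equal length")
        if np.any(u < 0):
            raise ValueError("uptake values must be non-negative")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "uptake", u)

    def __len__(self) -> int:
        return len(self.times_min)


@dataclass(frozen=True)
class UptakeRateResult:
    """OLS fit of uptake vs incubation time: the uptake rate and its uncertainty."""

    roi_id: int
    slope: float
    intercept: float
    slope_stderr: float
    r_squared: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def extract_uptake_series(
    stack: ImageStack,
    roi_mask: np.ndarray,
    calib: PlateCalibration = DEFAULT_CALIBRATION,
    nuclide: NuclideSpec = F18,
    reference_min: float = 0.0,
    psl_floor: float = 1.0,
) -> "dict[int, UptakeSeries]":
    """Per-ROI decay-corrected uptake series from a PSL stack and a label mask.

    For each frame the ROI statistic is the mean over pixels of the
    PSL->dose conversion, divided by the exposure duration
    (-> nGy/pixel/min) and multiplied by the frame's decay-correction
    factor relative to ``reference_min`` (default: start of incubation).
    """
    mask = np.asarray(roi_mask)
    if mask.shape != stack.shape:
        raise ValueError(f"mask shape {mask.shape} does not match frame shape {stack.shape}")
    labels = np.unique(mask)
    labels = labels[labels != 0]
    if labels.size == 0:
        raise ValueError("roi_mask contains no non-zero labels")

    factors = np.array(
        [
            decay_correction_factor(start, dur, nuclide, reference_min)
            for start, dur in stack.schedule.frames
        ]
    )
    durations = stack.schedule.durations
    midpoints = stack.schedule.midpoints

    dose_frames = [psl_image_to_dose(f, calib, psl_floor=psl_floor) for f in stack.frames]
    out: dict[int, UptakeSeries] = {}
    for label in labels:
        sel = mask == label
        if not np.any(sel):
            raise ValueError(f"ROI label {label} selects no pixels")
        values = np.array([d[sel].mean() for d in dose_frames]) / durations * factors
        out[int(label)] = UptakeSeries(roi_id=int(label), times_min=midpoints, uptake=values)
    return out


def fit_uptake_rate(series: UptakeSeries) -> UptakeRateResult:
    """Uptake rate as the OLS slope of uptake on frame midpoint time."""
    if len(series) < 2:
        raise ValueError("at least 2 frames are required to fit an uptake rate")
    t = series.times_min
    if np.ptp(t) == 0:
        raise ValueError("frame times have zero variance; cannot fit a slope")
    y = series.uptake
    if np.ptp(y) == 0:
        # Constant series: exact zero slope; linregress would warn on zero variance.
        return UptakeRateResult(series.roi_id, 0.0, float(y[0]), 0.0, 0.0, len(series))
    fit = sps.linregress(t, y)
    return UptakeRateResult(
        roi_id=series.roi_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_stderr=float(fit.stderr),
        r_squared=float(fit.rvalue) ** 2,
        n_frames=len(series),
    )


class UptakeModel:
    """Uptake-rate regression model over one or more ROI series.

    Construct with :meth:`from_stack` (image stack + ROI label mask) or
    :meth:`from_dataframe` (tidy long table), then call :meth:`fit`.
    """

    def __init__(self, series: Mapping[int, UptakeSeries]):
        if not series:
            raise ValueError("UptakeModel requires at least one uptake series")
        self.series = dict(series)

    @classmethod
    def from_stack(
        cls,
        stack: ImageStack,
        roi_mask: np.ndarray,
        calib: PlateCalibration = DEFAULT_CALIBRATION,
        nuclide: NuclideSpec = F18,
        reference_min: float = 0.0,
        psl_floor: float = 1.0,
    ) -> "UptakeModel":
        return cls(extract_uptake_series(stack, roi_mask, calib, nuclide, reference_min, psl_floor))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        roi_col: str = "roi_id",
        time_col: str = "time_min",
        value_col: str = "uptake_nGy_per_pixel_per_min",
    ) -> "UptakeModel":
        for col in (roi_col, time_col, value_col):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r} in uptake table")
        series = {
            int(roi): UptakeSeries(
                roi_id=int(roi),
                times_min=sub[time_col].to_numpy(float),
                uptake=sub[value_col].to_numpy(float),
            )
            for roi, sub in df.groupby(roi_col)
        }
        return cls(series)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "roi_id": s.roi_id,
                "time_min": t,
                "uptake_nGy_per_pixel_per_min": u,
            }
            for s in self.series.values()
            for t, u in zip(s.times_min, s.uptake)
        ]
        return pd.DataFrame(rows)

    def fit(self) -> "UptakeResults":
        return UptakeResults(self, {roi: fit_uptake_rate(s) for roi, s in self.series.items()})


class UptakeResults:
    """Fitted uptake rates with uncertainties and diagnostics."""

    def __init__(self, model: UptakeModel, fits: Mapping[int, UptakeRateResult]):
        self.model = model
        self.fits = dict(fits)

    @property
    def params(self) -> pd.Series:
        return pd.Series({roi: f.slope for roi, f in self.fits.items()}, name="slope")

    @property
    def bse(self) -> pd.Series:
        return pd.Series({roi: f.slope_stderr for roi, f in self.fits.items()}, name="slope_stderr")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "roi_id": f.roi_id,
                    "uptake_rate_dnGy_per_pixel_per_min": f.slope,
                    "uptake_rate_stderr_dnGy_per_pixel_per_min": f.slope_stderr,
                    "intercept_nGy_per_pixel_per_min": f.intercept,
                    "r_squared": f.r_squared,
                    "n_frames": f.n_frames,
                }
                for f in self.fits.values()
            ]
        ).sort_values("roi_id", ignore_index=True)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Uptake rate fits (uptake vs incubation time, OLS)",
            "=" * 64,
            f"{'ROI':>5} {'rate dnGy/px/min':>18} {'std err':>10} {'R^2':>8} {'frames':>7}",
            "-" * 64,
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{int(r.roi_id):>5} {r.uptake_rate_dnGy_per_pixel_per_min:>18.5g} "
                f"{r.uptake_rate_stderr_dnGy_per_pixel_per_min:>10.3g} {r.r_squared:>8.4f} "
                f"{int(r.n_frames):>7}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_fit(self, roi_ids: Sequence[int] | None = None, ax=None):
        """Scatter the uptake series and overlay the fitted lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rois = list(roi_ids) if roi_ids is not None else list(self.fits)
        for roi in rois:
            s = self.model.series[roi]
            f = self.fits[roi]
            pts = ax.plot(s.times_min, s.uptake, "o", label=f"ROI {roi}")
            tt = np.linspace(s.times_min.min(), s.times_min.max(), 50)
            ax.plot(tt, f.intercept + f.slope * tt, "-", color=pts[0].get_color())
        ax.set_xlabel("incubation time (min)")
        ax.set_ylabel("[18F]FDG uptake (nGy/pixel/min)")
        ax.legend(fontsize="small")
        return ax


def attenuation_thickness_map(
    background_psl: np.ndarray,
    time_zero_tissue_psl: np.ndarray,
    calib: PlateCalibration = DEFAULT_CALIBRATION,
    mu_per_um: float = 0.0025,
    psl_floor: float = 1.0,
) -> np.ndarray:
    """Per-pixel tissue thickness (um) from transmission attenuation.

    Analogous to PET transmission scans: the no-tissue (background) image
    and the no-uptake tissue image (at time zero) differ by the factor
    exp(-mu * thickness), so thickness = ln(D_bg / D_tissue) / mu after
    PSL -> dose conversion.  Pixels where the tissue dose meets or exceeds
    the background report 0; pixels with no usable background (or tissue
    signal below the plate floor) are NaN.
    """
    if mu_per_um <= 0:
        raise ValueError("mu_per_um must be > 0")
    bg = np.asarray(background_psl)
    ti = np.asarray(time_zero_tissue_psl)
    if bg.shape != ti.shape:
        raise ValueError(f"image shapes differ: {bg.shape} vs {ti.shape}")
    d_bg = psl_image_to_dose(bg, calib, psl_floor=psl_floor)
    d_ti = psl_image_to_dose(ti, calib, psl_floor=psl_floor)
    out = np.full(bg.shape, np.nan)
    ok = (d_bg > 0) & (d_ti > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.log(d_bg / d_ti) / mu_per_um
    out[ok] = np.maximum(t[ok], 0.0)
    return out


def relative_to_control(
    rates: Mapping[str, Sequence[float]],
    control_label: str,
) -> pd.DataFrame:
    """Percent-of-control per condition with SEM propagated from both groups.

    percent = 100 * mean(group) / mean(control); the SEM combines the
    relative SEMs of group and control in quadrature.
    """
    if control_label not in rates:
        raise ValueError(f"control label {control_label!r} not present")
    control = np.asarray(rates[control_label], dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    c_mean = control.mean()
    if c_mean == 0:
        raise ValueError("control mean is zero; percent-of-control undefined")
    c_rel_sem = (sps.sem(control) / abs(c_mean)) if control.size > 1 else 0.0

    rows = []
    for label, values in rates.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {label!r} is empty")
        pct = 100.0 * v.mean() / c_mean
        g_rel_sem = (sps.sem(v) / abs(v.mean())) if (v.size > 1 and v.mean() != 0) else 0.0
        rows.append(
            {
                "condition": label,
                "n": v.size,
                "percent_of_control": pct,
                "sem_percent": abs(pct) * math.hypot(g_rel_sem, c_rel_sem),
            }
        )
    return pd.DataFrame(rows)
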