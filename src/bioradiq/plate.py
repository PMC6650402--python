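"""Radioluminography plate response model.

Storage-phosphor (CR) plates report photostimulated luminescence (PSL),
which is logarithmic in absorbed dose for this plate family: PSL readings
saturate at high activity while the underlying dose keeps growing linearly.
The manufacturer's correction formula converts a PSL reading into its
80 kV X-ray equivalent dose in nGy,

    nGy = dose_scale * 10**((PSL - psl_offset) / psl_per_decade
                            - log10(sensitivity_ratio)),

with plate constants dose_scale = 8770 nGy, psl_offset = 1535 PSL,
psl_per_decade = 1024 PSL and sensitivity_ratio = 1.25 (the ratio of the
plate's beta+ sensitivity to its 80 kV X-ray sensitivity).  ``log`` in the
printed formula is base 10; the /psl_per_decade term writes the response in
decades.  The exact algebraic inverse is used by the simulator to render
plate readouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlateCalibration",
    "DEFAULT_CALIBRATION",
    "psl_to_dose",
    "dose_to_psl",
    "psl_image_to_dose",
    "normalize_rate",
]


@dataclass(frozen=True)
class PlateCalibration:
    """Constants of the plate's logarithmic PSL <-> nGy response.

    Parameters
    ----------
    dose_scale : float
        Dose (nGy) at the exponent's zero point.
    psl_offset : float
        PSL reading subtracted before the decade scaling.
    psl_per_decade : float
        PSL increment corresponding to one decade of dose.
    sensitivity_ratio : float
        Beta+/X-ray sensitivity ratio (>= 1, dimensionless).
    """

    dose_scale: float = 8770.0
    psl_offset: float = 1535.0
    psl_per_decade: float = 1024.0
    sensitivity_ratio: float = 1.25

    def __post_init__(self) -> None:
        for name in ("dose_scale", "psl_offset", "psl_per_decade", "sensitivity_ratio"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"PlateCalibration.{name} must be strictly positive, got {value!r}")
        if self.sensitivity_ratio < 1:
            raise ValueError(
                f"PlateCalibration.sensitivity_ratio must be >= 1, got {self.sensitivity_ratio!r}"
            )


DEFAULT_CALIBRATION = PlateCalibration()


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def _maybe_scalar(arr: np.ndarray, like) -> "np.ndarray | float":
    if np.isscalar(like) or (isinstance(like, np.ndarray) and like.ndim == 0):
        return float(arr)
    return arr


def psl_to_dose(psl, calib: PlateCalibration = DEFAULT_CALIBRATION):
    """Convert a PSL reading into its 80 kV X-ray equivalent dose (nGy).

    Strictly increasing and convex in PSL: equal PSL steps correspond to
    multiplicative dose steps, which is why raw PSL saturates against
    activity while the converted dose is linear.
    """
    arr = _as_float_array(psl, "psl")
    exponent = (arr - calib.psl_offset) / calib.psl_per_decade - math.log10(calib.sensitivity_ratio)
    return _maybe_scalar(calib.dose_scale * 10.0**exponent, psl)


def dose_to_psl(dose, calib: PlateCalibration = DEFAULT_CALIBRATION):
    """Exact algebraic inverse of :func:`psl_to_dose`.

    Requires dose > 0; a dose decade corresponds to exactly
    ``psl_per_decade`` PSL.
    """
    arr = _as_float_array(dose, "dose")
    if np.any(arr <= 0):
        raise ValueError("dose must be strictly positive")
    psl = calib.psl_offset + calib.psl_per_decade * (
        np.log10(arr / calib.dose_scale) + math.log10(calib.sensitivity_ratio)
    )
    return _maybe_scalar(psl, dose)


def psl_image_to_dose(
    image,
    calib: PlateCalibration = DEFAULT_CALIBRATION,
    psl_floor: float = 1.0,
):
    """Convert a PSL pixel array (e.g. 16-bit TIFF) to dose (nGy).

    Pixels at or below ``psl_floor`` are below the plate's representable
    floor (the simulator encodes zero dose there) and decode to 0 nGy
    rather than to the spurious small dose the unclamped formula would
    assign.
    """
    arr = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite PSL values")
    dose = psl_to_dose(np.maximum(arr, psl_floor), calib)
    return np.where(arr > psl_floor, dose, 0.0)


def normalize_rate(total, n_pixels: int, exposure_min: float):
    """Normalize an ROI-summed quantity to a per-pixel-per-minute rate."""
    if n_pixels < 1:
        raise ValueError(f"n_pixels must be >= 1, got {n_pixels}")
    if exposure_min <= 0:
        raise ValueError(f"exposure_min must be > 0, got {exposure_min}")
    return total / (n_pixels * exposure_min)
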