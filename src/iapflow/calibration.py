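"""Densitometric and scintillation-counting calibration.

Tissue side: autoradiographic film optical density (OD, arbitrary
units) is mapped to tissue activity (nCi/g) through a curve fitted to
precalibrated standards — by default monotone piecewise-linear
interpolation that reproduces every standard exactly, optionally an
ordinary-least-squares line.  The standards' OD range defines the
trusted support; queries outside it raise by default and can be clamped
behind an explicit flag.

Blood side: scintillation counts (cpm) from timed arterial samples are
quench-corrected to dpm via a counting efficiency (supplied directly or
as a linear function of a quench index) and converted to nCi/ml using
1 nCi = 2220 dpm and the sample volume (10 µl by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import CalibrationError, CalibrationRangeError, ValidationError

__all__ = [
    "DPM_PER_NCI",
    "CalibrationStandard",
    "CalibrationCurve",
    "RegionDensitySet",
    "RegionActivity",
    "BloodSampleCounts",
    "fit_calibration",
    "region_activity",
    "counts_to_concentration",
]

logger = logging.getLogger(__name__)

#: Disintegrations per minute per nanocurie.
DPM_PER_NCI = 2220.0

#: Default minimum number of density readings per region.
MIN_READINGS = 8


@dataclass(frozen=True)
class CalibrationStandard:
    """One precalibrated standard: known activity and its measured OD."""

    activity: float        # nCi/g
    optical_density: float  # arbitrary units

    def __post_init__(self) -> None:
        if self.activity <= 0:
            raise ValidationError("standard activity must be > 0")
        if self.optical_density <= 0:
            raise ValidationError("standard optical density must be > 0")


@dataclass
class CalibrationCurve:
    """Monotone map from optical density to tissue activity (nCi/g).

    ``mode`` is ``"interpolating"`` (piecewise linear through every
    standard) or ``"linear"`` (OLS fit, with ``r_squared`` reported).
    ``extrapolation`` is ``"error"`` (default) or ``"clamp"``.
    """

    mode: str
    od: np.ndarray        # sorted ascending
    activity: np.ndarray  # co-monotone with od
    extrapolation: str = "error"
    slope: Optional[float] = None
    intercept: Optional[float] = None
    r_squared: Optional[float] = None

    @property
    def support(self) -> tuple[float, float]:
        """Trusted OD range: [min, max] over the standards."""
        return float(self.od[0]), float(self.od[-1])

    @property
    def activity_range(self) -> tuple[float, float]:
        return float(self.activity.min()), float(self.activity.max())

    def __call__(self, od):
        od_arr = np.asarray(od, dtype=float)
        lo, hi = self.support
        out_of_range = (od_arr < lo) | (od_arr > hi)
        if np.any(out_of_range):
            if self.extrapolation == "clamp":
                od_arr = np.clip(od_arr, lo, hi)
            else:
                bad = np.atleast_1d(od_arr)[np.atleast_1d(out_of_range)]
                raise CalibrationRangeError(
                    f"optical density {bad.ravel()[0]:.6g} outside the "
                    f"standards' trusted range [{lo:.6g}, {hi:.6g}] "
                    f"(activities {self.activity_range[0]:.4g}-"
                    f"{self.activity_range[1]:.4g} nCi/g); pass "
                    "extrapolation='clamp' to clip instead"
                )
        if self.mode == "linear":
            result = self.slope * od_arr + self.intercept
        else:
            result = np.interp(od_arr, self.od, self.activity)
        return float(result) if np.isscalar(od) else result


def fit_calibration(
    standards: Sequence[CalibrationStandard],
    mode: str = "interpolating",
    *,
    extrapolation: str = "error",
) -> CalibrationCurve:
    """Fit the OD → activity map from precalibrated standards.

    Standards must have distinct optical densities and be co-monotone
    (higher OD ↔ higher activity, as film darkening increases with
    exposure); otherwise a :class:`CalibrationError` is raised.
    """
    if mode not in ("interpolating", "linear"):
        raise ValidationError(f"unknown calibration mode {mode!r}")
    if extrapolation not in ("error", "clamp"):
        raise ValidationError(f"unknown extrapolation policy {extrapolation!r}")
    if len(standards) < 2:
        raise ValidationError("calibration needs at least 2 standards")
    od = np.array([s.optical_density for s in standards], dtype=float)
    act = np.array([s.activity for s in standards], dtype=float)
    order = np.argsort(od)
    od, act = od[order], act[order]
    if np.any(np.diff(od) == 0):
        raise ValidationError("duplicate optical-density values among standards")
    if np.any(np.diff(act) < 0):
        raise CalibrationError(
            "standards are not co-monotone: activity decreases with "
            "increasing optical density"
        )
    curve = CalibrationCurve(mode=mode, od=od, activity=act, extrapolation=extrapolation)
    if mode == "linear":
        fit = sps.linregress(od, act)
        curve.slope = float(fit.slope)
        curve.intercept = float(fit.intercept)
        curve.r_squared = float(fit.rvalue**2)
    return curve


@dataclass
class RegionDensitySet:
    """Optical-density readings for one brain region of one animal."""

    region: str
    readings: np.ndarray

    def __post_init__(self) -> None:
        self.readings = np.asarray(self.readings, dtype=float)
        if self.readings.ndim != 1 or self.readings.size == 0:
            raise ValidationError("readings must be a non-empty 1-D sequence")


@dataclass(frozen=True)
class RegionActivity:
    """Calibrated activity of a region: value at the mean OD, plus spread."""

    region: str
    activity: float               # nCi/g at the mean optical density
    per_reading: np.ndarray       # calibrated value of each reading
    sd: float                     # SD of the per-reading values
    n: int


def region_activity(
    densities: RegionDensitySet,
    curve: CalibrationCurve,
    min_readings: int = MIN_READINGS,
) -> RegionActivity:
    """Calibrated tissue concentration for a set of density readings.

    The reported activity is the calibrated value of the mean OD; the
    per-reading calibrated values and their SD are returned alongside
    as a dispersion diagnostic.  Fewer than ``min_readings`` readings
    (8 by default) is a validation error.
    """
    n = densities.readings.size
    if n < min_readings:
        raise ValidationError(
            f"region {densities.region!r} has {n} density readings; at "
            f"least {min_readings} are required"
        )
    per_reading = np.asarray(curve(densities.readings), dtype=float)
    value = float(curve(float(densities.readings.mean())))
    return RegionActivity(
        region=densities.region,
        activity=value,
        per_reading=per_reading,
        sd=float(per_reading.std(ddof=1)),
        n=int(n),
    )


@dataclass(frozen=True)
class BloodSampleCounts:
    """Raw scintillation counts for one timed arterial blood sample."""

    animal_id: str
    time_s: float
    cpm: float
    efficiency: Optional[float] = None   # counting efficiency in (0, 1]
    quench_index: Optional[float] = None
    volume_ml: float = 0.010             # 10 µl samples

    def __post_init__(self) -> None:
        if self.cpm < 0:
            raise ValidationError("counts must be >= 0")
        if self.efficiency is not None and not (0 < self.efficiency <= 1):
            raise ValidationError("counting efficiency must be in (0, 1]")
        if self.volume_ml <= 0:
            raise ValidationError("sample volume must be > 0")


def counts_to_concentration(
    sample: BloodSampleCounts,
    quench_coefficients: Optional[tuple[float, float]] = None,
) -> float:
    """Blood tracer concentration (nCi/ml) from raw counts.

    Quench correction divides cpm by the counting efficiency to obtain
    dpm; efficiency comes from the sample itself, or from a linear
    quench curve ``efficiency = a + b·quench_index`` (clipped to (0, 1])
    when ``quench_coefficients`` are given, and defaults to 1.0 (no
    correction) with a logged warning otherwise.
    """
    eff = sample.efficiency
    if eff is None and quench_coefficients is not None and sample.quench_index is not None:
        a, b = quench_coefficients
        eff = min(a + b * sample.quench_index, 1.0)
        if eff <= 0:
            raise ValidationError(
                f"quench curve gives non-positive efficiency {eff:.4g} at "
                f"quench index {sample.quench_index}"
            )
    if eff is None:
        logger.warning(
            "no counting efficiency for sample %s@%ss; assuming 1.0 (no quench correction)",
            sample.animal_id, sample.time_s,
        )
        eff = 1.0
    dpm = sample.cpm / eff
    return dpm / DPM_PER_NCI / sample.volume_ml
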