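"""Fraction-number → hydrodynamic-size calibration and the AF4 schedule.

Each AF4 batch gets one quadratic calibration fitted to the per-fraction
DLS diameters; substituting fraction numbers into the quadratic puts all
batches on a common hydrodynamic size scale even when retention times
shift by 1–3 fractions between batches.  The module also carries the
elution schedule (fraction collection times and outlet flow, from which
fraction volumes follow) and the exponential-decay cross-flow program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .analytes import UnitError

#: Plausible DLS range for serum lipoprotein fractions, nm; points outside
#: are treated as instrument artifacts and dropped before fitting.
DLS_QC_RANGE_NM = (3.0, 80.0)


class CalibrationError(ValueError):
    """Raised when a size calibration cannot be fitted."""


@dataclass(frozen=True)
class QuadraticCalibration:
    """d(f) = c0 + c1*f + c2*f**2, diameter in nm, f = fraction number."""

    c0: float
    c1: float
    c2: float
    batch_id: str = ""
    n_points: int = 0
    rms_residual_nm: float = 0.0
    fraction_range: tuple[float, float] = (1.0, 40.0)
    monotone: bool = True

    def predict(self, fraction_number, extrapolation_margin: float = 2.0):
        """Predict hydrodynamic diameter(s) for fraction number(s).

        Fractions beyond the fitted range plus ``extrapolation_margin``
        raise a warning (the prediction is still returned).
        """
        f = np.asarray(fraction_number, dtype=float)
        lo, hi = self.fraction_range
        if np.any((f < lo - extrapolation_margin) | (f > hi + extrapolation_margin)):
            warnings.warn(
                "predicting size outside the fitted fraction range "
                f"[{lo}, {hi}] ± {extrapolation_margin}",
                stacklevel=2,
            )
        d = self.c0 + self.c1 * f + self.c2 * f**2
        return float(d) if np.isscalar(fraction_number) else d

    def inverse(self, diameter_nm: float) -> float:
        """Fraction number at which the quadratic reaches ``diameter_nm``.

        Uses the increasing branch; values outside the calibrated diameter
        range are clipped to the end fractions (mirrors the purge behaviour
        where everything larger elutes into the last fractions).
        """
        lo, hi = self.fraction_range
        if self.c2 == 0.0:
            if self.c1 == 0.0:
                raise CalibrationError("degenerate (constant) calibration")
            f = (diameter_nm - self.c0) / self.c1
        else:
            disc = self.c1**2 - 4.0 * self.c2 * (self.c0 - diameter_nm)
            if disc < 0:
                return hi if diameter_nm > self.predict(hi) else lo
            root = np.sqrt(disc)
            f1 = (-self.c1 + root) / (2.0 * self.c2)
            f2 = (-self.c1 - root) / (2.0 * self.c2)
            # pick the root on the increasing branch inside/nearest the range
            mid = 0.5 * (lo + hi)
            f = f1 if abs(f1 - mid) <= abs(f2 - mid) else f2
        return float(np.clip(f, lo, hi))


def fit_size_calibration(
    points: Iterable[tuple[float, float]],
    batch_id: str = "",
    qc_range_nm: tuple[float, float] = DLS_QC_RANGE_NM,
) -> QuadraticCalibration:
    """Ordinary least-squares quadratic fit of diameter vs fraction number.

    Points with non-finite diameters or diameters outside ``qc_range_nm``
    are excluded before fitting.  At least three distinct fraction numbers
    must survive QC.  A non-monotone fit over the fitted range is flagged
    with a warning but still returned.
    """
    pts = [(float(f), float(d)) for f, d in points]
    usable = [
        (f, d)
        for f, d in pts
        if np.isfinite(d) and qc_range_nm[0] < d < qc_range_nm[1]
    ]
    if len({f for f, _ in usable}) < 3:
        raise CalibrationError(
            f"need >=3 usable DLS points to fit a calibration, got {len(usable)}"
        )
    f = np.array([p[0] for p in usable])
    d = np.array([p[1] for p in usable])
    c2, c1, c0 = np.polyfit(f, d, 2)
    resid = d - (c0 + c1 * f + c2 * f**2)
    rms = float(np.sqrt(np.mean(resid**2)))
    lo, hi = float(f.min()), float(f.max())
    grid = np.linspace(lo, hi, 200)
    deriv = c1 + 2.0 * c2 * grid
    monotone = bool(np.all(deriv >= -1e-12))
    if not monotone:
        warnings.warn(
            f"size calibration for batch {batch_id!r} is not monotone over "
            f"fractions [{lo:g}, {hi:g}]",
            stacklevel=2,
        )
    return QuadraticCalibration(
        c0=float(c0),
        c1=float(c1),
        c2=float(c2),
        batch_id=batch_id,
        n_points=len(usable),
        rms_residual_nm=rms,
        fraction_range=(lo, hi),
        monotone=monotone,
    )


def predict_size(
    calibration: QuadraticCalibration, fraction_number, extrapolation_margin: float = 2.0
):
    """Functional alias for :meth:`QuadraticCalibration.predict`."""
    return calibration.predict(fraction_number, extrapolation_margin)


# --- size binning -----------------------------------------------------------

#: (region lower edge nm, bin width nm); regions tile (0, inf).
BIN_REGIONS = ((0.0, 1.0), (18.0, 2.0), (30.0, 3.0))


def assign_size_bin(diameter_nm: float) -> tuple[float, float]:
    """Assign a diameter to its half-open integer-edge size bin.

    Bins are 1 nm wide below 18 nm, 2 nm wide in [18, 30) and 3 nm wide
    from 30 nm up; edges are integers aligned to the region boundaries at
    18 and 30 nm.  Returns ``(lower_edge, width)``; the bin covers
    ``[lower_edge, lower_edge + width)``.
    """
    if not np.isfinite(diameter_nm) or diameter_nm <= 0:
        raise UnitError(f"diameter must be positive, got {diameter_nm}")
    if diameter_nm < 18.0:
        lower, width = np.floor(diameter_nm), 1.0
    elif diameter_nm < 30.0:
        lower, width = 18.0 + 2.0 * np.floor((diameter_nm - 18.0) / 2.0), 2.0
    else:
        lower, width = 30.0 + 3.0 * np.floor((diameter_nm - 30.0) / 3.0), 3.0
    return float(lower), float(width)


def bin_label(diameter_nm: float) -> str:
    lower, width = assign_size_bin(diameter_nm)
    return f"[{lower:g},{lower + width:g})"


# --- elution schedule and cross-flow program --------------------------------


@dataclass(frozen=True)
class ElutionSchedule:
    """Fraction-collection schedule of one AF4 run.

    The default program collects 38 fractions at 2.5 min increments
    (5–95 min) followed by 2 purge fractions at 4 min increments, with a
    nominal 0.1 mL/min outlet flow.
    """

    focus_time_min: float = 12.0
    collect_start_delay_min: float = 5.0
    increments: tuple[tuple[int, float], ...] = ((38, 2.5), (2, 4.0))
    outlet_flow_ml_min: float = 0.1
    measured_flow_trace_ml_min: tuple[float, ...] | None = None

    @property
    def n_fractions(self) -> int:
        return sum(count for count, _ in self.increments)

    @property
    def increment_minutes(self) -> np.ndarray:
        return np.concatenate(
            [np.full(count, minutes) for count, minutes in self.increments]
        )


def fraction_volumes(schedule: ElutionSchedule) -> np.ndarray:
    """Per-fraction collected volumes in mL.

    Volume = collection time increment × outlet flow rate; a measured
    flow trace (one value per fraction) takes precedence over the nominal
    outlet flow.
    """
    increments = schedule.increment_minutes
    if schedule.measured_flow_trace_ml_min is not None:
        flows = np.asarray(schedule.measured_flow_trace_ml_min, dtype=float)
        if flows.shape != increments.shape:
            raise UnitError(
                f"measured flow trace has {flows.size} values for "
                f"{increments.size} fractions"
            )
        if np.any(~np.isfinite(flows)):
            raise UnitError("measured flow trace contains missing values")
    else:
        flows = np.full_like(increments, schedule.outlet_flow_ml_min)
    return increments * flows


@dataclass(frozen=True)
class CrossflowProgram:
    """Exponential-decay gradient cross-flow, mL/min.

    F(t) = F_start - (F_start - F_end) * (t / t_end)**exponent
    """

    f_start_ml_min: float = 3.5
    f_end_ml_min: float = 0.0
    t_end_min: float = 90.0
    exponent: float = 0.8

    def __post_init__(self) -> None:
        if not (self.f_start_ml_min >= self.f_end_ml_min >= 0.0):
            raise UnitError("require f_start >= f_end >= 0")


def crossflow_at(t_min: float, program: CrossflowProgram = CrossflowProgram()) -> float:
    """Cross-flow rate at elution time ``t_min``.

    Past ``t_end`` the cross flow is off (purge phase): returns ``f_end``
    with a warning.
    """
    if t_min < 0:
        raise UnitError(f"time must be non-negative, got {t_min}")
    if t_min > program.t_end_min:
        warnings.warn(
            f"t={t_min} min is past the gradient end ({program.t_end_min} min); "
            "cross flow is off during the purge",
            stacklevel=2,
        )
        return program.f_end_ml_min
    frac = (t_min / program.t_end_min) ** program.exponent
    return program.f_start_ml_min - (program.f_start_ml_min - program.f_end_ml_min) * frac
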