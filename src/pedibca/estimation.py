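"""Estimation chain: from weight, height, age, sex and sensor-derived
quantities to the six body-composition parameters.

The device computes, in order: weight from the calibrated load cell, BMI,
body-fat percentage from a BMI/age/sex equation, fat-free mass from the
impedance index H²/Z, muscle mass from H²/R with sex and age corrections,
total body water from a near-infrared absorption term, and bone mass as a
weight/height linear form minus muscle mass.  All equations are evaluated
exactly as published; physiologically implausible outputs (negative bone
mass, body fat outside [0, 100]%) are flagged with a warning rather than
rejected, because the published forms can produce them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

from .errors import DomainError, EstimationStageError
from .sensor_models import (
    LoadCellCalibration,
    RawSensorFrame,
    adc_to_weight,
    make_optical_reading,
)

# CDC categories plus "normal" (the study's label for its healthy-weight group).
GROUP_LABELS = ("underweight", "healthy", "normal", "overweight", "obese", "unknown")

#: Parameters of the body-fat percentage equation: BF% = a*BMI - b*age - c*sex + d
BF_BMI_COEF, BF_AGE_COEF, BF_SEX_COEF, BF_INTERCEPT = 1.15, 0.7, 3.6, 1.4


class PhysiologicalRangeWarning(UserWarning):
    """An estimated parameter falls outside its plausible physiological range."""


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics for one child: age (years), sex (0 girl / 1 boy), height (cm)."""

    subject_id: str
    age_years: float
    sex_code: int
    height_cm: float
    group_label: str = "unknown"

    def __post_init__(self):
        if self.sex_code not in (0, 1):
            raise DomainError(f"sex_code must be 0 (girl) or 1 (boy), got {self.sex_code}")
        if self.height_cm <= 0:
            raise DomainError(f"height must be positive, got {self.height_cm} cm")
        if self.age_years <= 0:
            raise DomainError(f"age must be positive, got {self.age_years} years")
        if self.group_label not in GROUP_LABELS:
            raise DomainError(f"unknown group label {self.group_label!r}")


@dataclass
class BodyComposition:
    """The six estimated parameters plus weight for one subject."""

    weight_kg: float
    bmi: float
    bf_pct: float
    ffm_kg: float
    tbw_kg: float
    mm_kg: float
    bm_kg: float
    flags: list = field(default_factory=list)

    def __post_init__(self):
        values = (self.weight_kg, self.bmi, self.bf_pct, self.ffm_kg,
                  self.tbw_kg, self.mm_kg, self.bm_kg)
        if not all(math.isfinite(v) for v in values):
            raise DomainError("all body-composition fields must be finite")
        if self.weight_kg <= 0:
            raise DomainError(f"weight must be positive, got {self.weight_kg} kg")
        if not (0.0 <= self.bf_pct <= 100.0):
            self.flags.append(f"bf_pct outside [0, 100]: {self.bf_pct:.3f}")
        if self.bm_kg < 0:
            self.flags.append(f"negative bone mass: {self.bm_kg:.3f} kg")
        for f in self.flags:
            warnings.warn(f, PhysiologicalRangeWarning, stacklevel=3)


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, kg/m²."""
    if height_m <= 0:
        raise DomainError(f"height must be positive, got {height_m} m")
    if weight_kg < 0:
        raise DomainError(f"weight must be non-negative, got {weight_kg} kg")
    return weight_kg / height_m**2


def bf_percent(bmi_value: float, age_years: float, sex_code: int) -> float:
    """Body-fat percentage: 1.15·BMI − 0.7·age − 3.6·sex + 1.4."""
    if bmi_value < 0:
        raise DomainError("BMI must be non-negative")
    if sex_code not in (0, 1):
        raise DomainError(f"sex_code must be 0 or 1, got {sex_code}")
    return (BF_BMI_COEF * bmi_value - BF_AGE_COEF * age_years
            - BF_SEX_COEF * sex_code + BF_INTERCEPT)


def ffm(height_cm: float, impedance_ohm: float, weight_kg: float) -> float:
    """Fat-free mass (kg) from the impedance index: 0.742·H²/Z + 0.151·W + 1.613."""
    if impedance_ohm <= 0:
        raise DomainError(f"impedance must be positive, got {impedance_ohm} Ω")
    return 0.742 * height_cm**2 / impedance_ohm + 0.151 * weight_kg + 1.613


def mm(height_cm: float, resistance_ohm: float, sex_code: int, age_years: float) -> float:
    """Muscle mass (kg): 0.401·H²/R + sex + 3.825 − 0.071·age + 5.102."""
    if resistance_ohm <= 0:
        raise DomainError(f"resistance must be positive, got {resistance_ohm} Ω")
    if sex_code not in (0, 1):
        raise DomainError(f"sex_code must be 0 or 1, got {sex_code}")
    return (height_cm**2 / resistance_ohm * 0.401 + sex_code + 3.825
            - 0.071 * age_years + 5.102)


LogBase = Literal["log10", "ln"]


def tbw(
    age_years: float,
    height_cm: float,
    weight_kg: float,
    optical_current_a: float,
    log_base: LogBase = "log10",
) -> float:
    """Total body water (kg) from age, height, weight and photocurrent.

    TBW = 0.698·age + 0.414·H − 0.491·W + 2.638·log(1/I_OC) + 14.61, with
    the logarithm base-10 by default (``log_base="ln"`` switches to the
    natural log for sensitivity analysis).
    """
    if optical_current_a <= 0:
        raise DomainError(f"optical current must be positive, got {optical_current_a} A")
    log = math.log10 if log_base == "log10" else math.log
    return (0.698 * age_years + 0.414 * height_cm - 0.491 * weight_kg
            + 2.638 * log(1.0 / optical_current_a) + 14.61)


def bm(weight_kg: float, height_cm: float, mm_kg: float) -> float:
    """Bone mass (kg): 0.328·W + 0.339·H − 29.533 − MM.

    A negative result is returned as-is (the published form can produce
    one); callers surface it via the composition's soft-range flags.
    """
    return 0.328 * weight_kg + 0.339 * height_cm - 29.533 - mm_kg


def classify_weight_status(bmi_for_age_percentile: float) -> str:
    """CDC weight-status category from a supplied BMI-for-age percentile.

    Below the 5th percentile → underweight; 5th–85th → healthy;
    85th–95th → overweight; at or above the 95th → obese.  The upper
    class wins at exact cut points.
    """
    p = bmi_for_age_percentile
    if not (0.0 <= p <= 100.0):
        raise DomainError(f"percentile must lie in [0, 100], got {p}")
    if p < 5.0:
        return "underweight"
    if p < 85.0:
        return "healthy"
    if p < 95.0:
        return "overweight"
    return "obese"


def _frame_weight(frame: RawSensorFrame, calib: Optional[LoadCellCalibration]) -> float:
    if frame.adc_counts is not None:
        if calib is None:
            raise EstimationStageError("weight", "ADC counts supplied without a calibration")
        return adc_to_weight(frame.adc_counts, calib)
    if frame.weight_kg is not None:
        return frame.weight_kg
    raise EstimationStageError("weight", "frame supplies neither ADC counts nor weight")


def _frame_impedance(frame: RawSensorFrame) -> float:
    if frame.z_ohm is None:
        raise EstimationStageError(
            "ffm", "frame supplies no impedance (z_ohm) for the fat-free-mass stage"
        )
    return frame.z_ohm


def _frame_optical_current(frame: RawSensorFrame) -> float:
    if frame.v_volts is not None and frame.v0_volts is not None:
        return make_optical_reading(
            frame.v_volts, frame.v0_volts, frame.responsivity
        ).optical_current_a
    if frame.optical_current_a is not None:
        return frame.optical_current_a
    raise EstimationStageError(
        "tbw", "frame supplies neither photodiode voltages nor an optical current"
    )


def estimate_all(
    profile: SubjectProfile,
    frame: RawSensorFrame,
    calib: Optional[LoadCellCalibration] = None,
    log_base: LogBase = "log10",
) -> BodyComposition:
    """Run the whole estimation chain for one subject.

    Height is converted cm→m only for BMI; every other equation receives
    centimetres.  The impedance magnitude doubles as the resistance input
    of the muscle-mass equation unless the frame carries a separate
    ``resistance_ohm``.  Component failures are re-raised with the stage
    name attached.
    """
    weight = _frame_weight(frame, calib)

    def staged(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except EstimationStageError:
            raise
        except DomainError as exc:
            raise EstimationStageError(stage, str(exc)) from exc

    bmi_value = staged("bmi", bmi, weight, profile.height_cm / 100.0)
    bf_value = staged("bf", bf_percent, bmi_value, profile.age_years, profile.sex_code)
    impedance = _frame_impedance(frame)
    ffm_value = staged("ffm", ffm, profile.height_cm, impedance, weight)
    resistance = frame.resistance_ohm if frame.resistance_ohm is not None else impedance
    mm_value = staged("mm", mm, profile.height_cm, resistance,
                      profile.sex_code, profile.age_years)
    i_oc = _frame_optical_current(frame)
    tbw_value = staged("tbw", tbw, profile.age_years, profile.height_cm,
                       weight, i_oc, log_base)
    bm_value = staged("bm", bm, weight, profile.height_cm, mm_value)
    return BodyComposition(
        weight_kg=weight,
        bmi=bmi_value,
        bf_pct=bf_value,
        ffm_kg=ffm_value,
        tbw_kg=tbw_value,
        mm_kg=mm_value,
        bm_kg=bm_value,
    )
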