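"""Forward models of the analyzer's three sensing front-ends.

The portable analyzer measures weight with a strain-gauge load cell read
through a 24-bit ADC (HX711), total-body-water-related optical absorption
with a 970 nm LED / OPT101 photodiode pair, and whole-body impedance with
an AD5933 sweep at 50 kHz and 0.25 mA excitation.  Everything here is
deterministic arithmetic: two-point ADC calibration, the Beer–Lambert
optical-density / transmission chain, photocurrent from responsivity, and
the impedance magnitude from the voltage drop across the load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

from .errors import (
    DegenerateCalibrationError,
    DomainError,
    InfiniteImpedanceError,
    InvalidReadingError,
)

#: Photodiode responsivity at 970 nm, A/W (datasheet constant).
DEFAULT_RESPONSIVITY = 0.42
#: Default excitation current for the impedance sweep, amperes (0.25 mA).
DEFAULT_EXCITATION_CURRENT = 0.25e-3
#: Default excitation frequency, Hz.
DEFAULT_FREQUENCY_HZ = 50_000.0
#: Wavelength of the water-absorption LED, nm.
DEFAULT_WAVELENGTH_NM = 970.0

#: Tolerance (kg) below zero before a computed weight is treated as a fault.
NEGATIVE_WEIGHT_TOLERANCE_KG = 1e-9


@dataclass(frozen=True)
class LoadCellCalibration:
    """Two-point linear calibration of the load-cell ADC.

    ``slope_m`` is kg per ADC count and ``offset_c`` (kg) anchors the
    zero-load reading to exactly 0 kg, so both reference points are
    reproduced bit-for-bit.
    """

    slope_m: float
    offset_c: float
    ref_zero_load_counts: float
    ref_load_kg: float
    ref_load_counts: float

    def __post_init__(self):
        if not math.isfinite(self.slope_m) or self.slope_m == 0.0:
            raise DegenerateCalibrationError(
                f"calibration slope must be finite and nonzero, got {self.slope_m}"
            )


@dataclass(frozen=True)
class OpticalReading:
    """One optical measurement: incident/detected voltages and derived quantities."""

    v0_volts: float
    v_volts: float
    od: float
    transmission_t: float
    optical_current_a: float
    responsivity: float = DEFAULT_RESPONSIVITY
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM

    def __post_init__(self):
        if self.v_volts <= 0 or self.v0_volts <= 0:
            raise DomainError("photodiode voltages must be positive")
        if abs(self.transmission_t - 10.0 ** (-self.od)) > 1e-12:
            raise DomainError("transmission inconsistent with optical density")


@dataclass(frozen=True)
class ImpedanceSweep:
    """One impedance measurement from the converter's frequency sweep."""

    v_out: float
    v_in: float
    z_ohm: float
    i_load_a: float = DEFAULT_EXCITATION_CURRENT
    frequency_hz: float = DEFAULT_FREQUENCY_HZ

    def __post_init__(self):
        if self.i_load_a <= 0:
            raise DomainError("excitation current must be positive")
        if self.frequency_hz <= 0:
            raise DomainError("excitation frequency must be positive")


@dataclass
class RawSensorFrame:
    """Raw (or simulated) signals for one subject.

    Any derived quantity may be supplied directly instead of its raw
    precursors; the estimation chain uses the raw signal when present and
    falls back to the direct value otherwise.
    """

    subject_id: str
    adc_counts: Optional[float] = None
    v0_volts: Optional[float] = None
    v_volts: Optional[float] = None
    z_ohm: Optional[float] = None
    resistance_ohm: Optional[float] = None
    i_load_a: float = DEFAULT_EXCITATION_CURRENT
    frequency_hz: float = DEFAULT_FREQUENCY_HZ
    weight_kg: Optional[float] = None
    optical_current_a: Optional[float] = None
    responsivity: float = DEFAULT_RESPONSIVITY
    metadata: dict = field(default_factory=dict)


def fit_load_cell_calibration(
    zero_load_counts: float, known_load_kg: float, known_load_counts: float
) -> LoadCellCalibration:
    """Fit the two-point calibration from a zero-load and a known-load reading.

    The slope is ``known_load_kg / (known_load_counts - zero_load_counts)``
    and the offset is chosen so the zero-load reading maps to exactly 0 kg.
    """
    if known_load_kg <= 0:
        raise DomainError(f"known load must be positive, got {known_load_kg} kg")
    if known_load_counts == zero_load_counts:
        raise DegenerateCalibrationError(
            "zero-load and known-load ADC readings coincide; cannot calibrate"
        )
    slope = known_load_kg / (known_load_counts - zero_load_counts)
    offset = slope * zero_load_counts
    return LoadCellCalibration(
        slope_m=slope,
        offset_c=offset,
        ref_zero_load_counts=zero_load_counts,
        ref_load_kg=known_load_kg,
        ref_load_counts=known_load_counts,
    )


def adc_to_weight(adc_counts: float, calib: LoadCellCalibration) -> float:
    """Convert an ADC count to kilograms: ``counts * slope - offset``.

    Raises :class:`InvalidReadingError` for results below zero beyond a
    small tolerance — a negative weight signals a sensor or calibration
    fault and is never clamped.
    """
    weight = adc_counts * calib.slope_m - calib.offset_c
    if weight < -NEGATIVE_WEIGHT_TOLERANCE_KG:
        raise InvalidReadingError(
            f"ADC reading {adc_counts} implies negative weight {weight:.6g} kg"
        )
    return max(weight, 0.0)


def optical_density(v_volts: float, v0_volts: float) -> float:
    """Optical density OD = -log10(V / V0) of the transmitted signal."""
    if v_volts <= 0 or v0_volts <= 0:
        raise DomainError("photodiode voltages must be positive for optical density")
    return -math.log10(v_volts / v0_volts)


def transmission(od: float) -> float:
    """Transmission factor T = 10^(-OD)."""
    if not math.isfinite(od):
        raise DomainError("optical density must be finite")
    return 10.0 ** (-od)


def reconstruct_voltage(v0_volts: float, transmission_t: float) -> float:
    """Recover the detected voltage V = V0 * T (consistency verification)."""
    if v0_volts <= 0:
        raise DomainError("initial voltage must be positive")
    if not (0.0 < transmission_t <= 1.0):
        raise DomainError(f"transmission must lie in (0, 1], got {transmission_t}")
    return v0_volts * transmission_t


def optical_current(v_volts: float, responsivity: float = DEFAULT_RESPONSIVITY) -> float:
    """Photocurrent I = responsivity * V, in amperes.

    The detected voltage is used as the operand of the responsivity
    multiplication, exactly as the device computes it.
    """
    if v_volts < 0:
        raise DomainError("detected voltage must be non-negative")
    return responsivity * v_volts


ImpedanceMode = Literal["printed", "conventional"]


def impedance_from_sweep(
    v_out: float,
    v_in: float,
    i_load_a: float = DEFAULT_EXCITATION_CURRENT,
    mode: ImpedanceMode = "printed",
) -> float:
    """Impedance magnitude from the sweep voltages.

    ``mode="printed"`` solves the device equation literally, giving
    Z = I_load / (V_out - V_in); ``mode="conventional"`` is the Ohm's-law
    form Z = (V_out - V_in) / I_load, which yields the ohm-scale values
    (hundreds of ohms for a child at 50 kHz) the body-composition
    equations expect.  The caller should record the mode used.
    """
    if i_load_a <= 0:
        raise DomainError("excitation current must be positive")
    dv = v_out - v_in
    if dv == 0:
        raise InfiniteImpedanceError(
            "zero voltage difference across the load: impedance undefined"
        )
    if mode == "printed":
        return i_load_a / dv
    if mode == "conventional":
        return dv / i_load_a
    raise DomainError(f"unknown impedance mode {mode!r}")


def make_optical_reading(
    v_volts: float,
    v0_volts: float,
    responsivity: float = DEFAULT_RESPONSIVITY,
) -> OpticalReading:
    """Run the full optical chain (OD, T, verified V, photocurrent) on one reading."""
    od = optical_density(v_volts, v0_volts)
    t = transmission(od)
    v_verified = reconstruct_voltage(v0_volts, t)
    i_oc = optical_current(v_verified, responsivity)
    return OpticalReading(
        v0_volts=v0_volts,
        v_volts=v_volts,
        od=od,
        transmission_t=t,
        optical_current_a=i_oc,
        responsivity=responsivity,
    )
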