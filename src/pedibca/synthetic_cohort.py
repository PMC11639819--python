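"""Virtual study cohorts and the sensor-chain inversion.

The validation study enrolled two groups of one hundred children each
(obese and normal weight status, half boys and half girls) and reports
per-group means ± SD for age, weight, height and the six composition
parameters.  This module samples virtual cohorts with exactly that
statistical structure from independent truncated normals (an explicit
modeling assumption — the study publishes no subject-level data or
covariance; an optional Gaussian-copula mode accepts a target
correlation matrix for stress tests), inverts the estimation chain back
to raw sensor frames so every pipeline stage can be exercised without
hardware, and simulates a pair of noisy virtual devices for the
agreement statistics.

Two sampling modes exist because the published group means are not
mutually consistent with the estimation equations (BMI, BF% and BM are
deterministic functions of the other parameters in the device, but the
printed means do not satisfy those identities).  ``marginal`` mode
reproduces the printed per-parameter means/SDs; ``chain`` mode samples
only the free quantities (age, sex, height, weight, FFM, TBW, MM) and
derives BMI, BF% and BM through the device equations, which makes the
sensor inversion an exact round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Literal, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InversionError, SpecError
from .estimation import BodyComposition, SubjectProfile, bf_percent, bm, bmi
from .sensor_models import (
    DEFAULT_RESPONSIVITY,
    LoadCellCalibration,
    RawSensorFrame,
)

PARAMETERS = ("age", "weight", "height", "bmi", "bf", "ffm", "tbw", "mm", "bm")
#: Free quantities of chain mode; the rest are derived through the device equations.
CHAIN_SAMPLED = ("age", "weight", "height", "ffm", "tbw", "mm")

#: Default truncation bounds keeping every parameter positive, body fat
#: physiologic, and the impedance/resistance inversions in-domain.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "age": (1.0, 18.0),
    "weight": (5.0, 120.0),
    "height": (50.0, 200.0),
    "bmi": (5.0, 60.0),
    "bf": (0.0, 60.0),
    "ffm": (10.0, 80.0),
    "tbw": (2.0, 60.0),
    "mm": (10.5, 60.0),
    "bm": (0.05, 6.0),
}

#: Default incident voltage for the optical inversion, volts.
DEFAULT_V0 = 0.5


def _reference_moments() -> Dict[str, Dict[str, Tuple[float, float]]]:
    """Published per-group (mean, sd) for every parameter."""
    text = resources.files("pedibca.data").joinpath("reference_cohort_summary.csv")
    df = pd.read_csv(text.open())
    out: Dict[str, Dict[str, Tuple[float, float]]] = {"obese": {}, "normal": {}}
    for row in df.itertuples():
        out["obese"][row.parameter] = (row.obese_mean, row.obese_sd)
        out["normal"][row.parameter] = (row.normal_mean, row.normal_sd)
    return out


def reference_correlation(parameters=PARAMETERS) -> pd.DataFrame:
    """Published obese-group Pearson correlation matrix, mirrored symmetric."""
    text = resources.files("pedibca.data").joinpath("reference_correlations.csv")
    df = pd.read_csv(text.open(), index_col=0)
    mat = df.to_numpy(dtype=float)
    low = np.tril(np.nan_to_num(mat))
    sym = low + low.T - np.diag(np.diag(low))
    out = pd.DataFrame(sym, index=df.index, columns=df.index)
    keep = [p for p in parameters if p in out.index]
    return out.loc[keep, keep]


@dataclass
class CohortSpec:
    """Sampling specification for one virtual cohort.

    ``moments`` maps group → parameter → (mean, sd); defaults are the
    published group statistics verbatim.  ``bounds`` are per-parameter
    truncation limits.  A bound pair excluding mean ± 4 SD is rejected
    as infeasible.
    """

    moments: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=_reference_moments
    )
    n_obese: int = 100
    n_normal: int = 100
    boy_fraction: float = 0.5
    bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_obese < 1 or self.n_normal < 1:
            raise SpecError("group sizes must be at least 1")
        if not (0.0 <= self.boy_fraction <= 1.0):
            raise SpecError("boy_fraction must lie in [0, 1]")
        for group, params in self.moments.items():
            for name, (mean, sd) in params.items():
                if sd < 0:
                    raise SpecError(f"{group}/{name}: SD must be non-negative")
                lo, hi = self.bounds.get(name, (-math.inf, math.inf))
                if hi < mean - 4 * sd or lo > mean + 4 * sd:
                    raise SpecError(
                        f"{group}/{name}: truncation bounds ({lo}, {hi}) exclude "
                        f"mean ± 4 SD ({mean} ± {4 * sd})"
                    )

    @classmethod
    def from_dict(cls, doc: dict) -> "CohortSpec":
        spec = cls()
        kwargs = {}
        for key in ("n_obese", "n_normal", "boy_fraction", "seed"):
            if key in doc:
                kwargs[key] = doc[key]
        if "moments" in doc:
            moments = {g: dict(spec.moments[g]) for g in spec.moments}
            for group, params in doc["moments"].items():
                for name, pair in params.items():
                    moments.setdefault(group, {})[name] = tuple(pair)
            kwargs["moments"] = moments
        if "bounds" in doc:
            bounds = dict(spec.bounds)
            bounds.update({k: tuple(v) for k, v in doc["bounds"].items()})
            kwargs["bounds"] = bounds
        return replace(spec, **kwargs)


@dataclass
class DevicePairSpec:
    """Measurement-error model for a pair of virtual devices.

    Independent zero-mean Gaussian error per device per parameter.  The
    default SDs put each device's relative error in the low single-digit
    percent range of the corresponding group means, matching the ±3%
    overall error band the reference validation reports.
    """

    error_sd_a: Dict[str, float] = field(
        default_factory=lambda: {
            "weight": 0.70, "bmi": 0.45, "bf": 0.60, "ffm": 0.50,
            "tbw": 0.40, "mm": 0.45, "bm": 0.02,
        }
    )
    error_sd_b: Dict[str, float] = field(
        default_factory=lambda: {
            "weight": 0.70, "bmi": 0.45, "bf": 0.60, "ffm": 0.50,
            "tbw": 0.40, "mm": 0.45, "bm": 0.02,
        }
    )
    seed: int = 0

    def __post_init__(self):
        for label, sds in (("a", self.error_sd_a), ("b", self.error_sd_b)):
            for name, sd in sds.items():
                if sd < 0:
                    raise SpecError(f"device {label}/{name}: error SD must be >= 0")


def _truncnorm_draw(rng, mean, sd, lo, hi, size):
    if sd == 0:
        if not (lo <= mean <= hi):
            raise SpecError(f"degenerate draw at {mean} outside bounds ({lo}, {hi})")
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _truncnorm_ppf(u, mean, sd, lo, hi):
    if sd == 0:
        return np.full_like(u, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _nearest_correlation(mat: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    w, v = np.linalg.eigh((mat + mat.T) / 2)
    w = np.clip(w, 1e-8, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


SamplingMode = Literal["marginal", "chain"]


def generate_cohort(
    spec: CohortSpec,
    mode: SamplingMode = "marginal",
    correlation: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Sample one virtual cohort.

    Returns a subject-level table with profile columns (subject_id,
    group_label, sex_code, age_years, height_cm) and the seven
    composition columns (weight, bmi, bf, ffm, tbw, mm, bm).  In
    ``marginal`` mode every parameter is drawn from its own truncated
    normal; in ``chain`` mode BMI, BF% and BM are derived through the
    device equations from the sampled free quantities.  ``correlation``
    (parameter × parameter) switches marginal-mode sampling to a
    Gaussian copula with that target — an extension for stress tests,
    not part of the published study design.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    sampled = PARAMETERS if mode == "marginal" else CHAIN_SAMPLED
    for group, n in (("obese", spec.n_obese), ("normal", spec.n_normal)):
        moments = spec.moments[group]
        n_boys = int(round(n * spec.boy_fraction))
        sex = np.array([1] * n_boys + [0] * (n - n_boys))
        cols: Dict[str, np.ndarray] = {}
        if correlation is not None and mode == "marginal":
            names = [p for p in sampled if p in correlation.index]
            corr = _nearest_correlation(
                correlation.loc[names, names].to_numpy(dtype=float)
            )
            z = rng.multivariate_normal(
                np.zeros(len(names)), corr, size=n, method="cholesky"
            )
            u = sps.norm.cdf(z)
            for j, name in enumerate(names):
                mean, sd = moments[name]
                lo, hi = spec.bounds.get(name, (-math.inf, math.inf))
                cols[name] = _truncnorm_ppf(u[:, j], mean, sd, lo, hi)
            for name in sampled:
                if name not in cols:
                    mean, sd = moments[name]
                    lo, hi = spec.bounds.get(name, (-math.inf, math.inf))
                    cols[name] = _truncnorm_draw(rng, mean, sd, lo, hi, n)
        else:
            for name in sampled:
                mean, sd = moments[name]
                lo, hi = spec.bounds.get(name, (-math.inf, math.inf))
                cols[name] = _truncnorm_draw(rng, mean, sd, lo, hi, n)
        if mode == "chain":
            h_m = cols["height"] / 100.0
            cols["bmi"] = cols["weight"] / h_m**2
            cols["bf"] = (1.15 * cols["bmi"] - 0.7 * cols["age"]
                          - 3.6 * sex + 1.4)
            cols["bm"] = (0.328 * cols["weight"] + 0.339 * cols["height"]
                          - 29.533 - cols["mm"])
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{group[0].upper()}{i:04d}" for i in range(n)],
                    "group_label": group,
                    "sex_code": sex,
                    "age_years": cols["age"],
                    "height_cm": cols["height"],
                    **{p: cols[p] for p in PARAMETERS if p not in ("age", "height")},
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def profile_from_row(row) -> SubjectProfile:
    """Build a SubjectProfile from one cohort-table row."""
    get = row.get if hasattr(row, "get") else lambda k, d=None: getattr(row, k, d)
    return SubjectProfile(
        subject_id=str(get("subject_id")),
        age_years=float(get("age_years")),
        sex_code=int(get("sex_code")),
        height_cm=float(get("height_cm")),
        group_label=str(get("group_label", "unknown")),
    )


def composition_from_row(row) -> BodyComposition:
    get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
    return BodyComposition(
        weight_kg=float(get("weight")),
        bmi=float(get("bmi")),
        bf_pct=float(get("bf")),
        ffm_kg=float(get("ffm")),
        tbw_kg=float(get("tbw")),
        mm_kg=float(get("mm")),
        bm_kg=float(get("bm")),
    )


def consistent_composition(
    profile: SubjectProfile, weight_kg: float, ffm_kg: float,
    tbw_kg: float, mm_kg: float,
) -> BodyComposition:
    """Complete a composition so the chain-determined fields satisfy the
    device equations exactly (the invertible domain of the sensor chain)."""
    bmi_value = bmi(weight_kg, profile.height_cm / 100.0)
    return BodyComposition(
        weight_kg=weight_kg,
        bmi=bmi_value,
        bf_pct=bf_percent(bmi_value, profile.age_years, profile.sex_code),
        ffm_kg=ffm_kg,
        tbw_kg=tbw_kg,
        mm_kg=mm_kg,
        bm_kg=bm(weight_kg, profile.height_cm, mm_kg),
    )


def invert_to_sensors(
    composition: BodyComposition,
    profile: SubjectProfile,
    calib: LoadCellCalibration,
    v0_volts: float = DEFAULT_V0,
    responsivity: float = DEFAULT_RESPONSIVITY,
) -> RawSensorFrame:
    """Invert the estimation chain to a raw sensor frame.

    Solves the fat-free-mass equation for impedance, the muscle-mass
    equation for resistance, the total-body-water equation for optical
    current, and the load-cell calibration for ADC counts.  When the
    implied detector voltage (photocurrent / responsivity) lies in
    (0, v0], the optical chain is inverted all the way to voltages;
    otherwise the frame carries the optical current directly (the
    published water equation routinely implies photocurrents far outside
    the physical range of the optical front-end, which the estimation
    chain accepts as a direct input).

    Running the estimation chain on the returned frame reproduces the
    sensor-determined fields exactly; the full seven-field round trip is
    exact on chain-consistent compositions.
    """
    w, h = composition.weight_kg, profile.height_cm
    adc_counts = (w + calib.offset_c) / calib.slope_m

    ffm_denom = composition.ffm_kg - 0.151 * w - 1.613
    if ffm_denom <= 0:
        raise InversionError(
            "impedance",
            f"fat-free mass {composition.ffm_kg:.3f} kg at or below the "
            f"weight-only floor {0.151 * w + 1.613:.3f} kg",
        )
    z_ohm = 0.742 * h**2 / ffm_denom

    mm_denom = (composition.mm_kg - profile.sex_code - 3.825
                + 0.071 * profile.age_years - 5.102)
    if mm_denom <= 0:
        raise InversionError(
            "resistance",
            f"muscle mass {composition.mm_kg:.3f} kg at or below the "
            "sex/age floor of the muscle-mass equation",
        )
    resistance_ohm = 0.401 * h**2 / mm_denom

    q = (composition.tbw_kg - 0.698 * profile.age_years - 0.414 * h
         + 0.491 * w - 14.61) / 2.638
    optical_current_a = 10.0 ** (-q)

    frame = RawSensorFrame(
        subject_id=profile.subject_id,
        adc_counts=adc_counts,
        z_ohm=z_ohm,
        resistance_ohm=resistance_ohm,
        optical_current_a=optical_current_a,
        responsivity=responsivity,
        metadata={"inverted": True, "v0_volts": v0_volts},
    )
    v_volts = optical_current_a / responsivity
    if 0.0 < v_volts <= v0_volts:
        frame.v_volts = v_volts
        frame.v0_volts = v0_volts
        frame.optical_current_a = None
    return frame


def invert_cohort(
    cohort: pd.DataFrame, calib: LoadCellCalibration, **kwargs
) -> pd.DataFrame:
    """Invert every cohort row to a sensor-frame table (one row per subject)."""
    rows = []
    for _, row in cohort.iterrows():
        frame = invert_to_sensors(
            composition_from_row(row), profile_from_row(row), calib, **kwargs
        )
        rows.append(
            {
                "subject_id": frame.subject_id,
                "adc_counts": frame.adc_counts,
                "v0_volts": frame.v0_volts,
                "v_volts": frame.v_volts,
                "z_ohm": frame.z_ohm,
                "resistance_ohm": frame.resistance_ohm,
                "i_load_a": frame.i_load_a,
                "frequency_hz": frame.frequency_hz,
                "optical_current_a": frame.optical_current_a,
            }
        )
    return pd.DataFrame(rows)


def simulate_device_pair(
    cohort: pd.DataFrame, pair_spec: DevicePairSpec
) -> pd.DataFrame:
    """Simulate two noisy devices measuring every subject.

    Returns a subject-level paired table (subject_id, parameter, group,
    device_a, device_b) with independent zero-mean Gaussian error per
    device per parameter; seeded and reproducible.
    """
    rng = np.random.default_rng(pair_spec.seed)
    params = [p for p in ("weight", "bmi", "bf", "ffm", "tbw", "mm", "bm")
              if p in cohort.columns]
    rows = []
    for param in params:
        truth = cohort[param].to_numpy(dtype=float)
        sd_a = pair_spec.error_sd_a.get(param, 0.0)
        sd_b = pair_spec.error_sd_b.get(param, 0.0)
        a = truth + rng.normal(0.0, sd_a, size=len(truth)) if sd_a else truth.copy()
        b = truth + rng.normal(0.0, sd_b, size=len(truth)) if sd_b else truth.copy()
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": cohort["subject_id"],
                    "parameter": param,
                    "group": cohort["group_label"],
                    "device_a": a,
                    "device_b": b,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def paired_means(subject_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a subject-level paired table to group-mean rows."""
    out = (
        subject_table.groupby(["parameter", "group"], as_index=False)[
            ["device_a", "device_b"]
        ].mean()
    )
    return out
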