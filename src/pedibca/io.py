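"""CSV/YAML/JSON I/O, run configuration and provenance.

All CSVs use the RFC 4180 dialect with "." as the decimal separator and
are written at full precision (reports apply the 2/3-decimal rounding of
the reference tables at presentation time only).  Every CLI run drops a
provenance JSON (config echo, seed, package version) next to its outputs
so any run is reproducible from its provenance block alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .errors import SchemaError
from .sensor_models import (
    DEFAULT_EXCITATION_CURRENT,
    DEFAULT_FREQUENCY_HZ,
    RawSensorFrame,
)
from .estimation import SubjectProfile

SUBJECT_COLUMNS = ("subject_id", "age_years", "sex_code", "height_cm", "group_label")
OPTIONAL_SUBJECT_COLUMNS = (
    "weight_kg", "z_ohm", "resistance_ohm", "optical_current_a",
    "bmi_for_age_percentile",
)
SENSOR_COLUMNS = (
    "subject_id", "adc_counts", "v0_volts", "v_volts", "z_ohm",
    "resistance_ohm", "i_load_a", "frequency_hz", "optical_current_a",
)
COMPOSITION_COLUMNS = (
    "subject_id", "weight_kg", "bmi", "bf_pct", "ffm_kg", "tbw_kg", "mm_kg", "bm_kg",
)
PAIRED_COLUMNS = ("parameter", "group", "device_a", "device_b")


@dataclass
class RunConfig:
    """Configuration for one CLI run."""

    command: str = "simulate"
    seed: int = 0
    n_obese: int = 100
    n_normal: int = 100
    impedance_mode: str = "conventional"
    log_base: str = "log10"
    icc_form: str = "ICC2"
    rounding: int = 3
    sampling_mode: str = "chain"
    verbosity: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: doc.pop(k) for k in list(doc)
                 if k in cls.__dataclass_fields__ and k != "extra"}
        return cls(**known, extra=doc)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "seed": self.seed,
            "n_obese": self.n_obese,
            "n_normal": self.n_normal,
            "impedance_mode": self.impedance_mode,
            "log_base": self.log_base,
            "icc_form": self.icc_form,
            "rounding": self.rounding,
            "sampling_mode": self.sampling_mode,
            "extra": self.extra,
        }


def write_provenance(out_path, config: RunConfig) -> Path:
    """Write the provenance block for a run next to its main output."""
    out_path = Path(out_path)
    prov = {
        "package": "pedibca",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
    }
    prov_path = out_path.with_suffix(out_path.suffix + ".provenance.json")
    prov_path.write_text(json.dumps(prov, indent=2) + "\n")
    return prov_path


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} CSV lacks column(s): {missing}", columns=missing)


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError("subjects CSV is empty")
    _require_columns(df, SUBJECT_COLUMNS, "subjects")
    return df


def read_sensor_frames(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError("sensor-frame CSV is empty")
    _require_columns(df, ("subject_id",), "sensor-frame")
    return df


def read_paired_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError("paired-measurement CSV is empty")
    _require_columns(df, PAIRED_COLUMNS, "paired-measurement")
    return df


def frame_from_row(row) -> RawSensorFrame:
    """Build a RawSensorFrame from one sensor CSV row; absent cells may be
    NaN or missing entirely."""
    def get(name, default=None):
        try:
            v = row[name]
        except (KeyError, IndexError):
            return default
        return default if pd.isna(v) else float(v)

    return RawSensorFrame(
        subject_id=str(row["subject_id"]),
        adc_counts=get("adc_counts"),
        v0_volts=get("v0_volts"),
        v_volts=get("v_volts"),
        z_ohm=get("z_ohm"),
        resistance_ohm=get("resistance_ohm"),
        i_load_a=get("i_load_a", DEFAULT_EXCITATION_CURRENT),
        frequency_hz=get("frequency_hz", DEFAULT_FREQUENCY_HZ),
        weight_kg=get("weight_kg"),
        optical_current_a=get("optical_current_a"),
    )


def profile_from_subject_row(row) -> SubjectProfile:
    return SubjectProfile(
        subject_id=str(row["subject_id"]),
        age_years=float(row["age_years"]),
        sex_code=int(row["sex_code"]),
        height_cm=float(row["height_cm"]),
        group_label=str(row.get("group_label", "unknown")),
    )


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one packaged reference table by short name.

    Available: ``cohort_summary``, ``device_validation``, ``correlations``,
    ``reliability`` — the published study tables stored verbatim
    (including their known internal inconsistencies).
    """
    fname = f"reference_{name}.csv"
    res = resources.files("pedibca.data").joinpath(fname)
    if not res.is_file():
        raise SchemaError(f"no packaged reference table named {name!r}")
    kwargs = {"index_col": 0} if name == "correlations" else {}
    return pd.read_csv(res.open(), **kwargs)


def device_validation_pairs() -> pd.DataFrame:
    """The packaged device-validation table in paired-measurement layout."""
    ref = load_reference_table("device_validation")
    return pd.DataFrame(
        {
            "parameter": ref["parameter"],
            "group": ref["group"],
            "device_a": ref["pbca_mean"],
            "device_b": ref["tbca_mean"],
        }
    )
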