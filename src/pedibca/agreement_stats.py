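"""Method-agreement statistics for device validation.

Two families live here.  The analyzer study's own metrics: per-row
accuracy (one minus the absolute relative deviation from the reference
device, as a percentage), a mean accuracy pooled over both weight-status
groups and all seven parameters, a mean average error on the same
pooling, and the symmetric percent difference used to contrast group
means.  And the standard method-comparison toolkit: Bland–Altman bias
and limits of agreement, ICC(2,1) with its F-distribution confidence
interval (delegated to pingouin), the SEM derived from it, and group
summaries with t-tests, Shapiro–Wilk normality checks and a Pearson
correlation matrix (delegated to scipy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError, DomainError

GROUPS = ("obese", "normal")
#: Parameters pooled by the mean-accuracy / mean-average-error metrics.
VALIDATION_PARAMETERS = ("weight", "bmi", "bf", "ffm", "tbw", "mm", "bm")


def accuracy(p_value: float, t_value: float) -> float:
    """Device accuracy in percent: (1 − |p − t| / t) × 100.

    ``p_value`` is the device under test, ``t_value`` the reference.
    Full precision is returned; round to 2 decimals for reporting.
    """
    if t_value == 0:
        raise DomainError("reference value must be nonzero")
    return (1.0 - abs(p_value - t_value) / abs(t_value)) * 100.0


def percent_difference(a: float, b: float) -> float:
    """Symmetric percent difference: |a − b| / ((a + b)/2) × 100."""
    denom = (a + b) / 2.0
    if denom == 0:
        raise DomainError("mean of the two values is zero; percent difference undefined")
    return abs(a - b) / abs(denom) * 100.0


def _check_paired_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"parameter", "group", "device_a", "device_b"}
    missing = required - set(table.columns)
    if missing:
        raise ContractError(f"paired table lacks column(s): {sorted(missing)}")
    by_group = {g: set(sub["parameter"]) for g, sub in table.groupby("group")}
    if len(by_group) != 2:
        raise ContractError(f"expected two groups, found {sorted(by_group)}")
    sets = list(by_group.values())
    if sets[0] != sets[1]:
        raise ContractError(
            "groups cover different parameter sets: "
            f"{sorted(sets[0] ^ sets[1])} unmatched"
        )
    return table


def mean_accuracy(table: pd.DataFrame) -> float:
    """Pooled mean accuracy: 100 − (Σ diff% over both groups) / (2 × n_parameters).

    ``diff%`` per row is ``100 − accuracy``; the divisor counts each
    parameter once per group (seven parameters → divisor 14 in the
    reference validation layout).
    """
    table = _check_paired_table(table)
    n_parameters = table["parameter"].nunique()
    diffs = [
        100.0 - accuracy(row.device_a, row.device_b) for row in table.itertuples()
    ]
    return 100.0 - sum(diffs) / (2.0 * n_parameters)


def mean_avg_error(table: pd.DataFrame) -> float:
    """Pooled mean absolute error: Σ|device_b − device_a| / (2 × n_parameters)."""
    table = _check_paired_table(table)
    n_parameters = table["parameter"].nunique()
    err = (table["device_b"] - table["device_a"]).abs().sum()
    return float(err) / (2.0 * n_parameters)


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    differences: np.ndarray
    means: np.ndarray


def bland_altman(pairs: Sequence[Tuple[float, float]]) -> BlandAltman:
    """Bland–Altman bias and 95% limits of agreement (bias ± 1.96 SD).

    ``pairs`` are per-subject (a, b) measurements; differences are a − b
    and the SD uses the n−1 denominator.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ContractError("need at least two (a, b) pairs for Bland–Altman")
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        differences=diffs,
        means=means,
    )


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    form: str


def icc(ratings: np.ndarray, form: str = "ICC2") -> IccResult:
    """Intraclass correlation of a subjects × raters matrix.

    Default form is ICC(2,1): two-way random effects, absolute
    agreement, single measures ("ICC2" in pingouin's naming).  "ICC3"
    selects the consistency form.  The 95% CI comes from the standard
    F-distribution method.
    """
    import pingouin as pg  # deferred: pingouin import is slow

    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ContractError("need at least 2 subjects and 2 raters")
    if np.isnan(mat).any():
        raise ContractError("rating matrix contains missing cells")
    n, k = mat.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": mat.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    )
    # accept both SPSS-style and McGraw–Wong labels
    label = {"ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)", "ICC1": "ICC(1,1)"}.get(form, form)
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    row = table.set_index("Type").loc[label]
    ci_low, ci_high = row[ci_col]
    return IccResult(
        icc=float(row["ICC"]), ci_low=float(ci_low), ci_high=float(ci_high), form=form
    )


def sem_from_icc(sd: float, icc_value: float) -> float:
    """Standard error of measurement: SD × sqrt(1 − ICC)."""
    if not (0.0 <= icc_value <= 1.0):
        raise DomainError(f"ICC must lie in [0, 1], got {icc_value}")
    if sd < 0:
        raise DomainError("SD must be non-negative")
    return sd * math.sqrt(1.0 - icc_value)


@dataclass
class AgreementReport:
    """Full device-comparison report for one paired-measurement table."""

    per_row: pd.DataFrame  # parameter, group, device_a, device_b, accuracy, abs_error
    mean_accuracy: float
    mean_avg_error: float
    bland_altman: Dict[str, BlandAltman] = field(default_factory=dict)
    icc: Dict[str, IccResult] = field(default_factory=dict)
    sem: Dict[str, float] = field(default_factory=dict)
    mean_difference: Dict[str, float] = field(default_factory=dict)
    paired_p: Dict[str, float] = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_row": [
                {
                    "parameter": r.parameter,
                    "group": r.group,
                    "device_a": r.device_a,
                    "device_b": r.device_b,
                    "accuracy": round(r.accuracy, 2),
                    "abs_error": r.abs_error,
                }
                for r in self.per_row.itertuples()
            ],
            "mean_accuracy": round(self.mean_accuracy, 2),
            "mean_avg_error": round(self.mean_avg_error, 3),
            "bland_altman": {
                k: {"bias": v.bias, "loa_low": v.loa_low, "loa_high": v.loa_high}
                for k, v in self.bland_altman.items()
            },
            "icc": {
                k: {"icc": v.icc, "ci95": [v.ci_low, v.ci_high], "form": v.form}
                for k, v in self.icc.items()
            },
            "sem": self.sem,
            "mean_difference": self.mean_difference,
            "paired_p": self.paired_p,
            "warnings": list(self.warnings),
        }


def agreement_report(
    table: pd.DataFrame,
    subject_level: Optional[pd.DataFrame] = None,
    icc_form: str = "ICC2",
) -> AgreementReport:
    """Assemble the full report.

    ``table`` is the mean-level paired table (parameter, group,
    device_a, device_b).  ``subject_level``, when given, carries
    repeated measures (subject_id, parameter, device_a, device_b) and
    enables Bland–Altman, ICC, SEM, mean difference and paired t-tests
    per parameter; without it only the accuracy-family metrics are
    computed.
    """
    table = _check_paired_table(table)
    per_row = table.copy()
    per_row["accuracy"] = [
        accuracy(r.device_a, r.device_b) for r in table.itertuples()
    ]
    per_row["abs_error"] = (table["device_a"] - table["device_b"]).abs()
    report = AgreementReport(
        per_row=per_row,
        mean_accuracy=mean_accuracy(table),
        mean_avg_error=mean_avg_error(table),
    )
    if subject_level is None:
        return report
    required = {"subject_id", "parameter", "device_a", "device_b"}
    missing = required - set(subject_level.columns)
    if missing:
        raise ContractError(f"subject-level table lacks column(s): {sorted(missing)}")
    for param, sub in subject_level.groupby("parameter"):
        a = sub["device_a"].to_numpy(dtype=float)
        b = sub["device_b"].to_numpy(dtype=float)
        if len(sub) < 2:
            report.warnings.append(
                f"{param}: fewer than 2 paired subjects; Bland–Altman/ICC skipped"
            )
            continue
        report.bland_altman[param] = bland_altman(np.column_stack([a, b]))
        icc_res = icc(np.column_stack([a, b]), form=icc_form)
        report.icc[param] = icc_res
        pooled_sd = float(np.concatenate([a, b]).std(ddof=1))
        report.sem[param] = sem_from_icc(pooled_sd, max(0.0, min(1.0, icc_res.icc)))
        report.mean_difference[param] = float(np.mean(a - b))
        report.paired_p[param] = float(sps.ttest_rel(a, b).pvalue)
    return report


@dataclass
class GroupSummary:
    """Per-group descriptive statistics with percent differences and tests."""

    table: pd.DataFrame  # parameter, mean/sd per group, pct_diff, t_p, shapiro_p per group
    correlations: Dict[str, pd.DataFrame]


def summarize_groups(
    records: pd.DataFrame,
    parameters: Iterable[str] = VALIDATION_PARAMETERS,
    group_col: str = "group_label",
) -> GroupSummary:
    """Group-mean summary in the validation study's layout.

    For each parameter: mean ± SD per group, the symmetric percent
    difference of the two group means, a Welch t-test p-value, and a
    Shapiro–Wilk normality p-value per group; plus a per-group Pearson
    correlation matrix (symmetric, unit diagonal).
    """
    if group_col not in records.columns:
        raise ContractError(f"records lack group column {group_col!r}")
    groups = sorted(records[group_col].unique())
    if len(groups) != 2:
        raise ContractError(
            f"percent difference requires exactly two groups, found {groups}"
        )
    parameters = [p for p in parameters if p in records.columns]
    rows = []
    for param in parameters:
        cells = {"parameter": param}
        means = {}
        for g in groups:
            x = records.loc[records[group_col] == g, param].to_numpy(dtype=float)
            if len(x) < 2:
                raise ContractError(f"group {g!r} has fewer than 2 subjects")
            means[g] = float(x.mean())
            cells[f"{g}_mean"] = means[g]
            cells[f"{g}_sd"] = float(x.std(ddof=1))
            cells[f"{g}_shapiro_p"] = float(sps.shapiro(x).pvalue) if len(x) >= 3 else np.nan
        a = records.loc[records[group_col] == groups[0], param]
        b = records.loc[records[group_col] == groups[1], param]
        cells["pct_diff"] = percent_difference(means[groups[0]], means[groups[1]])
        cells["t_p"] = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(cells)
    corrs = {
        g: records.loc[records[group_col] == g, parameters].corr(method="pearson")
        for g in groups
    }
    return GroupSummary(table=pd.DataFrame(rows), correlations=corrs)
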