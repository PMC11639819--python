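"""Cross-parameter linear prediction models.

The analyzer's validation study reports one stepwise ordinary-least-squares
model per body-composition parameter, each predicting that parameter from
the other five.  This module exposes the published coefficient sets as
fixed artifacts, plus OLS refitting of the same model forms (via
statsmodels) and a deterministic stepwise driver with SPSS-style
enter/remove thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ContractError, DomainError, SingularDesignError

PARAMETERS = ("BMI", "BF", "FFM", "TBW", "MM", "BM")
_ALLOWED_PREDICTORS = set(PARAMETERS) | {"weight"}


@dataclass
class LinearModel:
    """One linear prediction model: intercept + named coefficients + diagnostics.

    ``standard_errors`` / ``t_stats`` / ``p_values`` are keyed by
    predictor name plus ``"intercept"``.  ``multiple_r`` and
    ``r_squared`` are stored verbatim for published models even where
    the pair is mutually inconsistent; they are metadata there, not
    quantities this package validates against each other.
    """

    response: str
    intercept: float
    coefficients: Dict[str, float]
    r_squared: Optional[float] = None
    multiple_r: Optional[float] = None
    f_stat: Optional[float] = None
    sig_f: Optional[float] = None
    standard_errors: Dict[str, float] = field(default_factory=dict)
    t_stats: Dict[str, float] = field(default_factory=dict)
    p_values: Dict[str, float] = field(default_factory=dict)
    n_obs: Optional[int] = None
    source: str = "fitted"

    def __post_init__(self):
        if self.source.startswith("published"):
            unknown = set(self.coefficients) - _ALLOWED_PREDICTORS
            if unknown:
                raise DomainError(f"unknown predictor(s): {sorted(unknown)}")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise DomainError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def to_json(self) -> str:
        doc = {
            "response": self.response,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "diagnostics": {
                "r_squared": self.r_squared,
                "multiple_r": self.multiple_r,
                "f_stat": self.f_stat,
                "sig_f": self.sig_f,
                "standard_errors": self.standard_errors,
                "t_stats": self.t_stats,
                "p_values": self.p_values,
                "n_obs": self.n_obs,
            },
            "source": self.source,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        doc = json.loads(text)
        diag = doc.get("diagnostics", {})
        return cls(
            response=doc["response"],
            intercept=doc["intercept"],
            coefficients=doc["coefficients"],
            r_squared=diag.get("r_squared"),
            multiple_r=diag.get("multiple_r"),
            f_stat=diag.get("f_stat"),
            sig_f=diag.get("sig_f"),
            standard_errors=diag.get("standard_errors", {}),
            t_stats=diag.get("t_stats", {}),
            p_values=diag.get("p_values", {}),
            n_obs=diag.get("n_obs"),
            source=doc.get("source", "fitted"),
        )


def _load_published() -> dict:
    text = resources.files("pedibca.data").joinpath("published_models.json").read_text()
    return json.loads(text)["models"]


ModelSource = Literal["table", "equation_text"]


def published_model(response: str, source: ModelSource = "table") -> LinearModel:
    """Return the published model for one response parameter.

    ``source="table"`` (default) is the canonical coefficient table with
    full diagnostics; ``source="equation_text"`` returns the variant as
    printed in the study's equation listing, which differs for two
    coefficients (BF model's BMI term, FFM model's BF term).
    """
    models = _load_published()
    if response not in models:
        raise DomainError(
            f"unknown response {response!r}; expected one of {sorted(models)}"
        )
    entry = models[response]
    if source in ("table", "table4"):  # "table4" kept as a legacy alias
        block = entry["table"]
        return LinearModel(
            response=response,
            intercept=block["intercept"],
            coefficients=dict(block["coefficients"]),
            r_squared=block["r_squared"],
            multiple_r=block["multiple_r"],
            f_stat=block["f_stat"],
            sig_f=block["sig_f"],
            standard_errors=dict(block["standard_errors"]),
            t_stats=dict(block["t_stats"]),
            p_values=dict(block["p_values"]),
            n_obs=200,
            source="published/table",
        )
    if source == "equation_text":
        block = entry["equation_text"]
        return LinearModel(
            response=response,
            intercept=block["intercept"],
            coefficients=dict(block["coefficients"]),
            source="published/equation-text",
        )
    raise DomainError(f"unknown source {source!r}")


def predict(model: LinearModel, values: Mapping[str, float]) -> float:
    """Evaluate the model: intercept + Σ coefficient × value."""
    missing = [name for name in model.coefficients if name not in values]
    if missing:
        raise ContractError(f"missing predictor value(s): {missing}")
    return model.intercept + sum(
        coef * values[name] for name, coef in model.coefficients.items()
    )


def _design(records: pd.DataFrame, response: str, predictors: Sequence[str]):
    missing = [c for c in (response, *predictors) if c not in records.columns]
    if missing:
        raise ContractError(f"records lack column(s): {missing}")
    y = records[response].to_numpy(dtype=float)
    X = records.loc[:, list(predictors)].to_numpy(dtype=float)
    return y, X


def fit_linear_model(
    records: pd.DataFrame, response: str, predictors: Sequence[str]
) -> LinearModel:
    """Ordinary-least-squares fit with intercept, reporting the published
    table's diagnostic layout (R², F, per-coefficient SE/t/p)."""
    predictors = list(predictors)
    y, X = _design(records, response, predictors)
    n, p = X.shape
    if n <= p + 1:
        raise SingularDesignError(
            f"need more observations ({n}) than predictors + intercept ({p + 1})"
        )
    if p and np.any(np.ptp(X, axis=0) == 0):
        constant = [predictors[j] for j in range(p) if np.ptp(X[:, j]) == 0]
        raise SingularDesignError(f"constant predictor column(s): {constant}")
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise SingularDesignError("rank-deficient design matrix")
    res = sm.OLS(y, exog).fit()
    names = ["intercept"] + predictors
    return LinearModel(
        response=response,
        intercept=float(res.params[0]),
        coefficients={name: float(b) for name, b in zip(predictors, res.params[1:])},
        r_squared=float(res.rsquared),
        multiple_r=float(np.sqrt(max(res.rsquared, 0.0))),
        f_stat=float(res.fvalue) if p else None,
        sig_f=float(res.f_pvalue) if p else None,
        standard_errors={n_: float(s) for n_, s in zip(names, res.bse)},
        t_stats={n_: float(t) for n_, t in zip(names, res.tvalues)},
        p_values={n_: float(pv) for n_, pv in zip(names, res.pvalues)},
        n_obs=int(n),
        source="fitted",
    )


def stepwise_fit(
    records: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> LinearModel:
    """Forward-selection / backward-elimination stepwise OLS.

    At each step the candidate with the smallest partial-F p-value enters
    if it beats ``p_enter`` (ties broken by smallest p, then alphabetical
    name); after every entry, included predictors whose p-value exceeds
    ``p_remove`` are dropped, worst first.  Deterministic for a given
    input table.  Thresholds default to the common enter-0.05 /
    remove-0.10 convention.
    """
    if not (0 < p_enter <= p_remove < 1):
        raise DomainError("require 0 < p_enter <= p_remove < 1")
    candidates = list(dict.fromkeys(candidates))
    included: List[str] = []

    def partial_p(predictor: str) -> float:
        model = fit_linear_model(records, response, included + [predictor])
        return model.p_values[predictor]

    while True:
        changed = False
        remaining = [c for c in candidates if c not in included]
        if remaining:
            scored = sorted(
                ((partial_p(c), c) for c in remaining), key=lambda t: (t[0], t[1])
            )
            best_p, best = scored[0]
            if best_p < p_enter:
                included.append(best)
                changed = True
        while len(included) > 0:
            model = fit_linear_model(records, response, included)
            worst = max(included, key=lambda c: (model.p_values[c], c))
            if model.p_values[worst] > p_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if not included:
        y = records[response].to_numpy(dtype=float)
        return LinearModel(
            response=response,
            intercept=float(np.mean(y)),
            coefficients={},
            r_squared=0.0,
            multiple_r=0.0,
            n_obs=len(y),
            source="fitted/stepwise",
        )
    model = fit_linear_model(records, response, included)
    model.source = "fitted/stepwise"
    return model
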