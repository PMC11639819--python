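"""Device-agreement metrics: the study's accuracy family and the
standard method-comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pedibca.agreement_stats import (
    accuracy,
    agreement_report,
    bland_altman,
    icc,
    mean_accuracy,
    mean_avg_error,
    percent_difference,
    sem_from_icc,
    summarize_groups,
)
from pedibca.errors import ContractError, DomainError
from pedibca.io import device_validation_pairs


def _single_param_table(diff_pct: float) -> pd.DataFrame:
    t = 100.0
    p = t * (1 - diff_pct / 100.0)
    return pd.DataFrame(
        {
            "parameter": ["x", "x"],
            "group": ["obese", "normal"],
            "device_a": [p, p],
            "device_b": [t, t],
        }
    )


class TestAccuracyFamily:
    @pytest.mark.parametrize(
        "p, t, expected",
        [(43.501, 42.746, 98.23), (29.511, 30.473, 96.84), (7.0, 7.0, 100.0)],
    )
    def test_accuracy(self, p, t, expected):
        assert round(accuracy(p, t), 2) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(DomainError):
            accuracy(1.0, 0.0)

    @given(
        p=st.floats(1.0, 100.0), t=st.floats(1.0, 100.0), k=st.floats(0.1, 10.0)
    )
    def test_accuracy_scale_invariant(self, p, t, k):
        assert accuracy(k * p, k * t) == pytest.approx(accuracy(p, t), abs=1e-9)

    def test_mean_accuracy_on_reference_table(self):
        assert round(mean_accuracy(device_validation_pairs()), 2) == 94.77

    def test_mean_avg_error_on_reference_table(self):
        assert round(mean_avg_error(device_validation_pairs()), 3) == 0.884

    def test_identical_devices(self):
        t = device_validation_pairs()
        t["device_a"] = t["device_b"]
        assert mean_accuracy(t) == pytest.approx(100.0)
        assert mean_avg_error(t) == pytest.approx(0.0)

    def test_single_parameter_definition(self):
        assert mean_accuracy(_single_param_table(10.0)) == pytest.approx(90.0)
        tbl = _single_param_table(0.0)
        tbl["device_a"] = tbl["device_b"] - 1.0
        assert mean_avg_error(tbl) == pytest.approx(1.0)

    def test_mean_accuracy_collapses_to_row_mean(self):
        table = device_validation_pairs()
        per_row = [100.0 - accuracy(r.device_a, r.device_b)
                   for r in table.itertuples()]
        assert mean_accuracy(table) == pytest.approx(
            100.0 - np.mean(per_row), abs=1e-9
        )

    def test_group_coverage_mismatch_rejected(self):
        t = device_validation_pairs().iloc[:-1]  # drop one normal row
        with pytest.raises(ContractError):
            mean_accuracy(t)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "a, b, expected, tol",
        [
            (43.501, 29.511, 38.322, 1e-3),
            (27.473, 22.431, 20.206, 1e-3),
            (5.0, 5.0, 0.0, 1e-12),
        ],
    )
    def test_values(self, a, b, expected, tol):
        assert percent_difference(a, b) == pytest.approx(expected, abs=tol)

    @given(a=st.floats(0.1, 100.0), b=st.floats(0.1, 100.0))
    def test_symmetry(self, a, b):
        assert percent_difference(a, b) == pytest.approx(
            percent_difference(b, a), abs=1e-12
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(DomainError):
            percent_difference(1.0, -1.0)


class TestBlandAltman:
    def test_constant_difference(self):
        ba = bland_altman([(2.0, 1.0), (5.0, 4.0), (9.0, 8.0)])
        assert ba.bias == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(1.0)
        assert ba.loa_high == pytest.approx(1.0)

    def test_identical_pairs(self):
        ba = bland_altman([(1, 1), (2, 2), (3, 3)])
        assert ba.bias == 0.0
        assert (ba.loa_low, ba.loa_high) == (0.0, 0.0)

    def test_hand_computed_sd(self):
        # differences (1, 2, 3): mean 2, sample SD exactly 1
        ba = bland_altman([(2.0, 1.0), (4.0, 2.0), (6.0, 3.0)])
        assert ba.bias == pytest.approx(2.0)
        assert ba.loa_low == pytest.approx(2.0 - 1.96)
        assert ba.loa_high == pytest.approx(2.0 + 1.96)

    def test_insufficient_data(self):
        with pytest.raises(ContractError):
            bland_altman([(1.0, 2.0)])

    def test_normal_coverage_near_95_percent(self):
        rng = np.random.default_rng(2024)
        d = rng.normal(size=10_000)
        ba = bland_altman(np.column_stack([d, np.zeros_like(d)]))
        frac = np.mean((ba.differences >= ba.loa_low)
                       & (ba.differences <= ba.loa_high))
        assert 0.94 <= frac <= 0.96


def _icc21_oracle(mat: np.ndarray) -> float:
    """ICC(2,1) from the explicit two-way ANOVA mean squares."""
    n, k = mat.shape
    grand = mat.mean()
    ms_rows = k * np.sum((mat.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((mat.mean(axis=0) - grand) ** 2) / (k - 1)
    resid = (mat - mat.mean(axis=1, keepdims=True)
             - mat.mean(axis=0, keepdims=True) + grand)
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )


class TestIcc:
    def test_duplicate_raters_give_unity(self):
        x = np.random.default_rng(1).normal(size=(10, 1))
        res = icc(np.hstack([x, x]))
        assert res.icc == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(8)
        res = icc(rng.normal(size=(1000, 2)))
        assert abs(res.icc) < 0.1

    def test_matches_anova_mean_squares_oracle(self):
        mat = np.array(
            [[9.0, 2.0], [8.0, 1.0], [7.0, 4.0], [10.0, 5.0], [6.0, 3.0]]
        )
        res = icc(mat, form="ICC2")
        assert res.icc == pytest.approx(_icc21_oracle(mat), abs=1e-9)

    def test_rater_shift_lowers_absolute_agreement_only(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(50, 1))
        mat = np.hstack([base, base + rng.normal(0, 0.1, size=(50, 1))])
        shifted = mat.copy()
        shifted[:, 1] += 2.0
        assert icc(shifted, "ICC2").icc < icc(mat, "ICC2").icc
        # with equal rater means the absolute-agreement estimate coincides
        # with the consistency form up to the O(k/n) rater-variance term
        balanced = mat - mat.mean(axis=0, keepdims=True)
        assert icc(balanced, "ICC2").icc == pytest.approx(
            icc(balanced, "ICC3").icc, abs=0.01
        )

    def test_missing_cells_rejected(self):
        mat = np.array([[1.0, 2.0], [np.nan, 1.0], [2.0, 2.0]])
        with pytest.raises(ContractError):
            icc(mat)


class TestSem:
    @pytest.mark.parametrize(
        "sd, r, expected", [(5.0, 1.0, 0.0), (1.0, 0.75, 0.5), (2.0, 0.96, 0.4)]
    )
    def test_values(self, sd, r, expected):
        assert sem_from_icc(sd, r) == pytest.approx(expected)

    def test_out_of_range_icc(self):
        with pytest.raises(DomainError):
            sem_from_icc(1.0, 1.2)


class TestSummaries:
    def _records(self, rng, n=30):
        return pd.DataFrame(
            {
                "group_label": ["obese"] * n + ["normal"] * n,
                "weight": np.r_[rng.normal(43.5, 0.7, n), rng.normal(29.5, 3.5, n)],
                "bmi": np.r_[rng.normal(24, 3.4, n), rng.normal(15.7, 1.6, n)],
            }
        )

    def test_group_means_reproduce_percent_difference(self):
        df = pd.DataFrame(
            {
                "group_label": ["obese"] * 2 + ["normal"] * 2,
                "weight": [43.501, 43.501, 29.511, 29.511],
            }
        )
        summary = summarize_groups(df, parameters=["weight"])
        row = summary.table.iloc[0]
        assert row["pct_diff"] == pytest.approx(38.322, abs=1e-3)

    def test_identical_groups_zero_diff(self):
        rng = np.random.default_rng(0)
        df = self._records(rng)
        df.loc[df.group_label == "normal", ["weight", "bmi"]] = (
            df.loc[df.group_label == "obese", ["weight", "bmi"]].to_numpy()
        )
        summary = summarize_groups(df, parameters=["weight", "bmi"])
        assert np.allclose(summary.table["pct_diff"], 0.0)

    def test_correlation_matrix_symmetric_unit_diagonal(self):
        summary = summarize_groups(
            self._records(np.random.default_rng(4)), parameters=["weight", "bmi"]
        )
        for corr in summary.correlations.values():
            assert np.allclose(corr, corr.T)
            assert np.allclose(np.diag(corr), 1.0)

    def test_single_group_rejected(self):
        df = pd.DataFrame({"group_label": ["obese"] * 4, "weight": [1.0, 2, 3, 4]})
        with pytest.raises(ContractError):
            summarize_groups(df, parameters=["weight"])


class TestAgreementReport:
    def test_full_report_on_reference_table(self):
        report = agreement_report(device_validation_pairs())
        assert round(report.mean_accuracy, 2) == 94.77
        assert round(report.mean_avg_error, 3) == 0.884
        assert (report.per_row["accuracy"] <= 100.0).all()

    def test_subject_level_block(self):
        rng = np.random.default_rng(3)
        truth = rng.normal(30, 3, size=40)
        sub = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(40)] * 2,
                "parameter": ["weight"] * 40 + ["bmi"] * 40,
                "device_a": np.r_[truth + rng.normal(0, 0.5, 40),
                                  truth + rng.normal(0, 0.5, 40)],
                "device_b": np.r_[truth + rng.normal(0, 0.5, 40),
                                  truth + rng.normal(0, 0.5, 40)],
            }
        )
        means = sub.copy()
        means["group"] = ["obese"] * 20 + ["normal"] * 20 + ["obese"] * 20 + [
            "normal"
        ] * 20
        mean_table = means.groupby(["parameter", "group"], as_index=False)[
            ["device_a", "device_b"]
        ].mean()
        report = agreement_report(mean_table, subject_level=sub)
        for param in ("weight", "bmi"):
            ba = report.bland_altman[param]
            assert ba.loa_low <= ba.bias <= ba.loa_high
            assert 0.0 <= report.paired_p[param] <= 1.0
            assert report.sem[param] >= 0.0
        doc = report.to_dict()
        assert doc["mean_accuracy"] == round(report.mean_accuracy, 2)
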