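"""Friedman gate, Wilcoxon and Mann-Whitney tests, median(Q1;Q3) summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from fetalhrv.errors import InsufficientDataError, ValidationError
from fetalhrv.stats import (
    HOURS,
    format_median_iqr,
    friedman,
    mann_whitney,
    median_iqr,
    summarize,
    wilcoxon_signed_rank,
)


class TestFriedman:
    def test_full_concordance_statistic(self):
        # five subjects ranking three timepoints identically -> chi2 = 10
        mat = np.tile([1.0, 2.0, 3.0], (5, 1)) + \
            np.arange(5)[:, None] * 10
        stat, p = friedman(mat, method="chisq")
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(sp_stats.chi2.sf(10.0, 2))

    def test_identical_columns_null(self):
        mat = np.tile([[4.0], [7.0], [9.0]], (1, 4))
        stat, p = friedman(mat)
        assert stat == 0.0 and p == 1.0

    def test_statistic_matches_scipy_on_random_data(self, rng):
        mat = rng.normal(0, 1, (8, 7))
        stat, _ = friedman(mat, method="chisq")
        ref = sp_stats.friedmanchisquare(*(mat[:, j] for j in range(7)))
        assert stat == pytest.approx(ref.statistic, rel=1e-9)

    def test_exact_small_design_p_in_unit_interval(self, rng):
        mat = rng.normal(0, 1, (3, 3))
        stat, p = friedman(mat, method="exact")
        assert 0 < p <= 1

    def test_shape_preconditions(self):
        with pytest.raises(ValidationError):
            friedman(np.ones((1, 4)))
        with pytest.raises(ValidationError):
            friedman(np.ones((5, 2)))


class TestWilcoxon:
    def test_all_positive_n5(self):
        p = wilcoxon_signed_rank([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert p == pytest.approx(2 / 32)  # exact two-sided

    def test_no_change_is_null(self):
        assert wilcoxon_signed_rank([1.0, 2.0, 3.0, 4, 5],
                                    [1.0, 2.0, 3.0, 4, 5]) == 1.0

    def test_too_few_nonzero_differences(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 6])


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_null(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestSummaries:
    def test_interpolated_quartiles(self):
        med, q1, q3 = median_iqr(range(1, 9))
        assert (med, q1, q3) == (4.5, 2.75, 6.25)

    def test_single_value_quartiles_collapse(self):
        assert median_iqr([7.0]) == (7.0, 7.0, 7.0)

    def test_formatting(self):
        assert format_median_iqr(range(1, 9)) == "4.5(2.75;6.25)"


def _cohort_frame(rng, effect_hours=(), effect=0.0, n_lps=8, n_control=7):
    """Long-format cohort with one variable; optional LPS-only effect."""
    rows = []
    for group, n in (("LPS", n_lps), ("Control", n_control)):
        for s in range(n):
            base = rng.normal(10, 1)
            for hour in HOURS:
                val = base + rng.normal(0, 0.5)
                if group == "LPS" and hour in effect_hours:
                    val += effect
                rows.append({"subject": f"{group}{s}", "group": group,
                             "timepoint": hour, "X": val})
    return pd.DataFrame(rows)


class TestSummarize:
    def test_report_shapes(self, rng):
        df = _cohort_frame(rng, effect_hours=("H2", "H3", "H4"), effect=5.0)
        report = summarize(df)
        assert len(report.summary) == 2 * 7  # groups x timepoints
        assert set(report.friedman["group"]) == {"Control", "LPS"}
        assert len(report.mannwhitney) == 7

    def test_wilcoxon_gate_blocks_null_variables(self, rng):
        """No within-group post-hoc p may appear for a variable whose
        Friedman screen did not reject."""
        df = _cohort_frame(rng)  # pure null
        report = summarize(df)
        gated = report.friedman.set_index(["variable", "group"])["p"]
        for _, row in report.wilcoxon.iterrows():
            assert gated.loc[(row["variable"], row["group"])] < 0.05

    def test_effect_is_detected_and_marked(self, rng):
        df = _cohort_frame(rng, effect_hours=("H2", "H3", "H4"), effect=5.0)
        report = summarize(df)
        fr = report.friedman.set_index(["variable", "group"])["p"]
        assert fr.loc[("X", "LPS")] < 0.05
        sig = report.wilcoxon[(report.wilcoxon["group"] == "LPS")
                              & report.wilcoxon["significant"]]
        assert {"H2", "H3", "H4"} <= set(sig["timepoint"])
        mw_sig = report.mannwhitney[report.mannwhitney["significant"]]
        assert {"H2", "H3", "H4"} <= set(mw_sig["timepoint"])
        table = report.format_table()
        assert "*" in table and "▲" in table

    def test_missing_variable_omitted(self, rng):
        df = _cohort_frame(rng)
        report = summarize(df, variables=["X", "NotThere"])
        assert report.variables == ["X"]

    def test_missing_key_columns_rejected(self):
        with pytest.raises(ValidationError):
            summarize(pd.DataFrame({"a": [1]}))

    def test_subject_with_missing_cell_excluded_from_friedman(self, rng):
        df = _cohort_frame(rng)
        df.loc[(df["subject"] == "LPS0") & (df["timepoint"] == "H3"),
               "X"] = np.nan
        from fetalhrv.stats import repeated_measures_matrix

        mat, subjects = repeated_measures_matrix(df, "X", "LPS")
        assert "LPS0" not in subjects and mat.shape == (7, 7)
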