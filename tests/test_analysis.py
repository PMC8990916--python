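"""BMI grouping, group summaries, ANOVA and paired tests, report."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ssdekit import (
    anova_across_groups,
    assign_bmi_group,
    build_report,
    group_summary,
    within_group_metric_test,
)
from ssdekit.analysis import (
    apply_ssde,
    metric_value,
    oneway_anova,
    paired_t,
    render_text,
)


class TestBmiGrouping:
    @pytest.mark.parametrize(
        "bmi,region,expected",
        [
            (19.9, "chest", "A"),
            (20.0, "chest", "B"),
            (24.9, "abdomen", "E"),  # boundary inclusive in middle group
            (24.95, "chest", "C"),
            (25.0, "abdomen", "F"),
            (17.0, "abdomen", "D"),
        ],
    )
    def test_cut_points(self, bmi, region, expected):
        assert assign_bmi_group(bmi, region) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            assign_bmi_group(-1.0, "chest")
        with pytest.raises(ValueError):
            assign_bmi_group(22.0, "thorax")


class TestGroupSummary:
    def test_sample_sd_hand_example(self, chest_records):
        # {2, 4}: mean 3, sample SD sqrt(2)
        vals = np.array([2.0, 4.0])
        assert vals.std(ddof=1) == pytest.approx(math.sqrt(2))
        s = group_summary(chest_records, "ed")
        assert s.loc["A", "n"] == 30
        assert s["mean"].is_monotonic_increasing  # size grows with BMI

    def test_empty_group_reported_with_nan(self, chest_records):
        thin = [r for r in chest_records if r.bmi >= 20.0]  # drop group A
        s = group_summary(thin, "ap")
        assert s.loc["A", "n"] == 0
        assert np.isnan(s.loc["A", "mean"])


class TestOnewayAnova:
    def test_hand_sums_of_squares(self):
        # groups {3,5} and {7,9}: MS_between=16, MS_within=2, F=8
        f, p = oneway_anova([np.array([3.0, 5.0]), np.array([7.0, 9.0])])
        assert f == pytest.approx(8.0)
        assert p == pytest.approx(stats.f.sf(8.0, 1, 2))

    def test_identical_groups_give_zero_f(self):
        g = np.array([1.0, 2.0])
        f, p = oneway_anova([g, g, g])
        assert f == 0.0
        assert p == 1.0

    def test_fully_separated_groups_drive_p_to_zero(self):
        f, p = oneway_anova(
            [np.array([0.0, 1e-6]), np.array([10.0, 10.0 + 1e-6])]
        )
        assert p < 1e-6

    def test_degenerate_equal_constants(self):
        f, p = oneway_anova([np.array([5.0, 5.0]), np.array([5.0, 5.0])])
        assert (f, p) == (0.0, 1.0)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([np.array([1.0, 2.0])])

    @settings(deadline=None, max_examples=50)
    @given(
        data=st.lists(
            st.lists(
                st.floats(min_value=-100, max_value=100),
                min_size=2, max_size=8,
            ),
            min_size=2, max_size=4,
        )
    )
    def test_matches_scipy_f_oneway(self, data):
        groups = [np.array(g) for g in data]
        if sum(g.var() for g in groups) == 0:
            return  # degenerate convention differs by design
        f, p = oneway_anova(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-9, abs=1e-9)
        if np.isfinite(ref.pvalue):  # scipy yields nan when SS_between ~ 0
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)


class TestPairedT:
    def test_hand_example(self):
        # differences {1,2,3}: t = 2 / (1/sqrt(3)) = 3.464
        res = paired_t(np.array([1.0, 2.0, 3.0]))
        assert res.t == pytest.approx(2.0 * math.sqrt(3), abs=1e-3)
        ref = stats.ttest_rel([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.p == pytest.approx(ref.pvalue)

    def test_exact_tie_flag(self):
        res = paired_t(np.zeros(5))
        assert res.tied
        assert res.t == 0.0

    def test_ssde_exceeds_ctdi_in_every_chest_group(self, chest_records):
        records = apply_ssde(list(chest_records))
        for label in ("A", "B", "C"):
            grp = [r for r in records if assign_bmi_group(r.bmi, "chest") == label]
            res = within_group_metric_test(grp, ("ssde_wed", "ctdi_vol"))
            assert res.t > 0 and res.p < 0.05

    def test_unpaired_variant_runs(self, chest_records):
        records = apply_ssde(list(chest_records))[:30]
        res = within_group_metric_test(
            records, ("ssde_ed", "ctdi_vol"), paired=False
        )
        assert not res.paired
        assert res.p < 0.05


class TestReport:
    def test_regional_dose_orderings(self, chest_records, abdomen_records):
        """Chest: SSDE_WED > SSDE_ED > CTDI_vol; abdomen reversed SSDEs."""
        records = apply_ssde(list(chest_records) + list(abdomen_records))
        report = build_report(records)
        ch = report["chest"].dose_table
        ab = report["abdomen"].dose_table
        for label in ("A", "B", "C"):
            row = ch.loc[label]
            assert (
                row[("ssde_wed", "mean")]
                > row[("ssde_ed", "mean")]
                > row[("ctdi_vol", "mean")]
            )
        for label in ("D", "E", "F"):
            row = ab.loc[label]
            assert (
                row[("ssde_ed", "mean")]
                > row[("ssde_wed", "mean")]
                > row[("ctdi_vol", "mean")]
            )

    def test_across_group_significance(self, abdomen_records):
        records = apply_ssde(list(abdomen_records))
        gc = build_report(records)["abdomen"]
        for metric in ("ed", "wed", "ctdi_vol", "ssde_ed", "ssde_wed"):
            assert gc.anova[metric][1] < 0.05

    def test_empty_cohort_yields_empty_report(self):
        assert build_report([]) == {}

    def test_missing_group_noted_not_crashed(self, chest_records):
        thin = apply_ssde([r for r in chest_records if r.bmi >= 24.0])
        report = build_report(thin)
        gc = report["chest"]
        assert any("excluded" in n or "skipped" in n for n in gc.notes)

    def test_text_rendering_contains_tables(self, chest_records):
        records = apply_ssde(list(chest_records))
        text = render_text(build_report(records))
        assert "chest: size metrics" in text
        assert "ssde_wed vs ctdi_vol" in text

    def test_bonferroni_tightens_alpha(self, chest_records):
        records = apply_ssde(list(chest_records))
        gc = build_report(records, bonferroni=True)["chest"]
        assert gc.alpha == pytest.approx(0.05 / 3)

    def test_anova_wrapper_matches_manual_grouping(self, chest_records):
        records = apply_ssde(list(chest_records))
        f, p = anova_across_groups(records, "ed")
        groups = [
            np.array([metric_value(r, "ed") for r in records
                      if assign_bmi_group(r.bmi, "chest") == g])
            for g in ("A", "B", "C")
        ]
        assert (f, p) == pytest.approx(oneway_anova(groups))
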