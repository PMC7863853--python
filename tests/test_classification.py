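import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from worry19 import (
    DichotomyConfig,
    Rationale,
    WorryGroup,
    build_group_tables,
    classify_full,
    classify_simplified,
    classify_table,
    combined_qol_impact,
)
from worry19.survey_io import LIKERT5

CFG = DichotomyConfig()
MISSING = None
LEVEL_OR_MISSING = st.sampled_from(list(LIKERT5) + [MISSING])


def rec(worried="yes", prec="yes", safer="very much", qw="not at all", qp="not at all"):
    return {
        "worried": worried,
        "takes_precautions": prec,
        "feel_safer": safer,
        "qol_worry": qw,
        "qol_precautions": qp,
    }


class TestCombinedQolImpact:
    @pytest.mark.parametrize(
        "qw, qp, expected",
        [
            ("not at all", "not at all", "none_or_little_both"),
            ("a little", "a little", "none_or_little_both"),
            ("not at all", "very much", "some_or_strong_either"),
            ("moderately", "not at all", "some_or_strong_either"),
            (MISSING, "not at all", "missing"),
            (MISSING, "very much", "some_or_strong_either"),  # one high answer decides
            (MISSING, MISSING, "missing"),
        ],
    )
    def test_dichotomy(self, qw, qp, expected):
        assert combined_qol_impact(qw, qp, CFG) == expected

    @given(qw=LEVEL_OR_MISSING, qp=LEVEL_OR_MISSING)
    @settings(deadline=None)
    def test_total_and_symmetric(self, qw, qp):
        out = combined_qol_impact(qw, qp, CFG)
        assert out in ("none_or_little_both", "some_or_strong_either", "missing")
        assert out == combined_qol_impact(qp, qw, CFG)


class TestFullClassification:
    def test_unworried_regardless_of_other_answers(self):
        g, r = classify_full(rec(worried="no", qp="very much"), CFG)
        assert g is WorryGroup.UNWORRIED and r is Rationale.NOT_WORRIED

    def test_functional_requires_all_three_conditions(self):
        g, r = classify_full(rec(), CFG)
        assert g is WorryGroup.FUNCTIONAL and r is Rationale.ALL_THREE_CONDITIONS

    def test_feel_safer_missing_is_dysfunctional(self):
        g, r = classify_full(rec(safer=MISSING), CFG)
        assert g is WorryGroup.DYSFUNCTIONAL and r is Rationale.SAFER_MISSING

    def test_no_precautions_is_dysfunctional_even_with_low_qol(self):
        g, r = classify_full(rec(prec="no"), CFG)
        assert g is WorryGroup.DYSFUNCTIONAL and r is Rationale.NO_PRECAUTIONS

    def test_not_feeling_safer_is_dysfunctional(self):
        g, r = classify_full(rec(safer="a little"), CFG)
        assert g is WorryGroup.DYSFUNCTIONAL and r is Rationale.NOT_SAFER

    def test_qol_reduced_is_dysfunctional(self):
        g, r = classify_full(rec(qp="moderately"), CFG)
        assert g is WorryGroup.DYSFUNCTIONAL and r is Rationale.QOL_REDUCED

    def test_worried_missing_is_unclassifiable(self):
        g, r = classify_full(rec(worried=MISSING), CFG)
        assert g is WorryGroup.UNCLASSIFIABLE and r is Rationale.WORRY_MISSING

    def test_missing_qol_policy_switch(self):
        record = rec(qw=MISSING)
        g, _ = classify_full(record, CFG)
        assert g is WorryGroup.DYSFUNCTIONAL
        alt = DichotomyConfig(missing_qol_policy="unclassifiable")
        g, r = classify_full(record, alt)
        assert g is WorryGroup.UNCLASSIFIABLE and r is Rationale.QOL_MISSING

    @given(
        worried=st.sampled_from(["yes", "no", MISSING]),
        prec=st.sampled_from(["yes", "no", MISSING]),
        safer=LEVEL_OR_MISSING,
        qw=LEVEL_OR_MISSING,
        qp=LEVEL_OR_MISSING,
    )
    @settings(deadline=None, max_examples=300)
    def test_monotone_dominance_of_unworriedness(self, worried, prec, safer, qw, qp):
        """Editing any record's worried answer to 'no' always yields UNWORRIED."""
        record = rec(worried, prec, safer, qw, qp)
        record["worried"] = "no"
        g, _ = classify_full(record, CFG)
        assert g is WorryGroup.UNWORRIED

    @given(
        worried=st.sampled_from(["yes", "no", MISSING]),
        prec=st.sampled_from(["yes", "no", MISSING]),
        safer=LEVEL_OR_MISSING,
        qw=LEVEL_OR_MISSING,
        qp=LEVEL_OR_MISSING,
    )
    @settings(deadline=None, max_examples=300)
    def test_scalar_and_vectorised_classifiers_agree(self, worried, prec, safer, qw, qp):
        record = rec(worried, prec, safer, qw, qp)
        g, r = classify_full(record, CFG)
        df = pd.DataFrame([record]).astype("string")
        out = classify_table(df, CFG)
        assert out.loc[0, "worry_group"] == g.value
        assert out.loc[0, "rationale_code"] == r.value
        gs, rs = classify_simplified(record, CFG)
        outs = classify_table(df, CFG, scheme="simplified")
        assert outs.loc[0, "worry_group"] == gs.value


class TestSimplifiedScheme:
    def test_ignores_precautions(self):
        record = rec(prec="no", qw="not at all")
        assert classify_full(record, CFG)[0] is WorryGroup.DYSFUNCTIONAL
        assert classify_simplified(record, CFG)[0] is WorryGroup.FUNCTIONAL

    def test_worry_qol_ceiling_is_dysfunctional(self):
        assert classify_simplified(rec(qw="very much"), CFG)[0] is WorryGroup.DYSFUNCTIONAL

    def test_unworried(self):
        assert classify_simplified(rec(worried="no"), CFG)[0] is WorryGroup.UNWORRIED

    @given(
        prec=st.sampled_from(["yes", "no"]),
        safer=LEVEL_OR_MISSING,
        qw=st.sampled_from(list(LIKERT5)),
        qp=st.sampled_from(list(LIKERT5)),
    )
    @settings(deadline=None, max_examples=200)
    def test_simplified_functional_contains_full_functional(self, prec, safer, qw, qp):
        """Every fully-functional respondent is simplified-functional too."""
        record = rec("yes", prec, safer, qw, qp)
        if classify_full(record, CFG)[0] is WorryGroup.FUNCTIONAL:
            assert classify_simplified(record, CFG)[0] is WorryGroup.FUNCTIONAL


class TestGroupTables:
    def test_fixture_reproduces_published_counts(self, fixture_table):
        tabs = build_group_tables(fixture_table, CFG)
        counts = dict(zip(tabs.group_counts["worry_group"], tabs.group_counts["n"]))
        assert counts == {"UNWORRIED": 401, "FUNCTIONAL": 203, "DYSFUNCTIONAL": 487}
        pct = dict(zip(tabs.group_counts["worry_group"], tabs.group_counts["pct"].round(0)))
        assert pct == {"UNWORRIED": 37, "FUNCTIONAL": 19, "DYSFUNCTIONAL": 45}

    def test_table2_cells_partition_the_worried_total(self, fixture_table):
        tabs = build_group_tables(fixture_table, CFG)
        t1 = tabs.worry_by_precaution.set_index("worry")
        t2 = tabs.precaution_by_qol
        assert t2["total"].sum() == t1.loc["worried", "n"] == 690

    def test_all_unworried_gives_degenerate_table(self, fixture_table):
        allun = fixture_table.copy()
        allun["worried"] = "no"
        tabs = build_group_tables(allun, CFG)
        counts = dict(zip(tabs.group_counts["worry_group"], tabs.group_counts["n"]))
        assert counts == {"UNWORRIED": 1091, "FUNCTIONAL": 0, "DYSFUNCTIONAL": 0}

    def test_weighted_twin_scales_counts(self, fixture_table):
        w = pd.Series(2.0, index=fixture_table.index)
        tabs = build_group_tables(fixture_table, CFG, weights=w)
        counts = dict(zip(tabs.group_counts["worry_group"], tabs.group_counts["n"]))
        assert counts == {"UNWORRIED": 802.0, "FUNCTIONAL": 406.0, "DYSFUNCTIONAL": 974.0}


def test_dichotomy_config_validates_closure():
    with pytest.raises(ValueError, match="upward-closed"):
        DichotomyConfig(feel_safer_positive_levels=("a little", "very much"))
    with pytest.raises(ValueError, match="downward-closed"):
        DichotomyConfig(qol_low_levels=("a little",))
    # alternative upward-closed cut is allowed (the published tables are
    # ambiguous about where the feel-safer cut sat)
    DichotomyConfig(feel_safer_positive_levels=("a little", "moderately", "quite a bit", "very much"))
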