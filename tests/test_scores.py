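import numpy as np
import pandas as pd
import pytest

from worry19 import (
    covid_impact_score,
    cronbach_alpha,
    emotion_item_codes,
    emotion_score,
    recode_emotion_binary,
    recode_risk_perception,
    reengagement_score,
)
from worry19.survey_io import (
    COMPLIANCE_ITEMS,
    EMOTION_ITEMS,
    EXPERIENCE_ITEMS,
    FREQ5,
    LIKERT5,
    POSITIVE_EMOTIONS,
)


def _exp_frame(yes_items=(), missing_items=()):
    row = {}
    for item in EXPERIENCE_ITEMS:
        row[item] = "yes" if item in yes_items else (pd.NA if item in missing_items else "no")
    return pd.DataFrame([row]).astype("string")


class TestImpactScore:
    @pytest.mark.parametrize(
        "yes, expected",
        [((), 0), (("exp_self_work_loss", "exp_lost_accommodation"), 2), (EXPERIENCE_ITEMS, 8)],
    )
    def test_sum_of_indicators(self, yes, expected):
        out = covid_impact_score(_exp_frame(yes))
        assert out.loc[0, "impact_score"] == expected
        assert not out.loc[0, "impact_any_missing"]

    def test_missing_counts_zero_but_is_flagged(self):
        out = covid_impact_score(_exp_frame(("exp_close_died",), ("exp_unable_pay_bills",)))
        assert out.loc[0, "impact_score"] == 1
        assert out.loc[0, "impact_any_missing"]

    def test_permutation_equivariance(self, big_panel):
        w2 = big_panel[0].head(500)
        perm = np.random.default_rng(0).permutation(len(w2))
        direct = covid_impact_score(w2)["impact_score"].to_numpy()
        permuted = covid_impact_score(w2.iloc[perm].reset_index(drop=True))["impact_score"].to_numpy()
        assert (permuted == direct[perm]).all()


def _emotion_frame(levels: dict):
    row = {item: levels.get(item, LIKERT5[0]) for item in EMOTION_ITEMS}
    return pd.DataFrame([row]).astype("string")


class TestEmotionScore:
    def test_binary_recode_keying(self):
        s = pd.Series(["not at all", "a little"], dtype="string")
        assert recode_emotion_binary(s, "emo_anxiety").tolist() == ["no", "yes"]
        assert recode_emotion_binary(s, "emo_happiness").tolist() == ["yes", "no"]
        with pytest.raises(ValueError):
            recode_emotion_binary(s, "emo_unknown")

    def test_floor_and_ceiling(self):
        best = _emotion_frame({p: LIKERT5[4] for p in POSITIVE_EMOTIONS})
        assert emotion_score(best).iloc[0] == 6
        worst = _emotion_frame(
            {**{n: LIKERT5[4] for n in ("emo_anxiety", "emo_anger", "emo_loneliness")},
             **{p: LIKERT5[0] for p in POSITIVE_EMOTIONS}}
        )
        assert emotion_score(worst).iloc[0] == 30

    def test_single_item_arithmetic(self):
        f = _emotion_frame({**{p: LIKERT5[4] for p in POSITIVE_EMOTIONS}, "emo_anxiety": LIKERT5[2]})
        assert emotion_score(f).iloc[0] == 8

    def test_missing_item_gives_missing_score(self):
        f = _emotion_frame({})
        f.loc[0, "emo_anger"] = pd.NA
        assert pd.isna(emotion_score(f).iloc[0])

    def test_reverse_key_involution(self):
        rng = np.random.default_rng(5)
        raw = pd.DataFrame(
            {i: np.asarray(LIKERT5, dtype=object)[rng.integers(0, 5, 50)] for i in EMOTION_ITEMS}
        ).astype("string")
        codes = emotion_item_codes(raw)
        # re-reversing the positive items restores the raw 1..5 coding
        level_code = {lvl: i + 1 for i, lvl in enumerate(LIKERT5)}
        for item in POSITIVE_EMOTIONS:
            raw_codes = raw[item].map(level_code).astype("Int64")
            assert ((6 - codes[item]) == raw_codes).all()

    def test_score_equals_bruteforce_sum(self, big_panel):
        w2 = big_panel[0].head(1000)
        total = emotion_score(w2)
        brute = emotion_item_codes(w2).astype(float).sum(axis=1)
        ok = total.notna()
        assert ok.all()
        assert np.allclose(total[ok].astype(float), brute[ok])
        assert total.astype(float).between(6, 30).all()


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        col = np.arange(10, dtype=float)
        X = np.column_stack([col] * 6)
        assert cronbach_alpha(X) == pytest.approx(1.0, abs=1e-12)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            X = rng.integers(1, 6, size=(10, 6)).astype(float)
            C = np.cov(X, rowvar=False, ddof=1)
            if C.sum() == 0:
                continue
            k = X.shape[1]
            oracle = (k / (k - 1)) * (1 - np.trace(C) / C.sum())
            assert cronbach_alpha(X) == pytest.approx(oracle, abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        X = rng.integers(1, 6, size=(40, 6)).astype(float)
        ref = pingouin.cronbach_alpha(data=pd.DataFrame(X))[0]
        assert cronbach_alpha(X) == pytest.approx(ref, abs=1e-10)

    def test_independent_items_give_near_zero(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(size=(10_000, 6))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_zero_variance_is_signalled(self):
        with pytest.raises(ValueError, match="variance"):
            cronbach_alpha(np.ones((10, 6)))


def _panel_waves(levels2, levels3):
    def frame(levels, rid=("a",)):
        row = {item: lvl for item, lvl in zip(COMPLIANCE_ITEMS, levels)}
        df = pd.DataFrame([{"respondent_id": r, **row} for r in rid])
        return df.astype("string")

    return frame(levels2), frame(levels3)


class TestReengagement:
    def test_no_change_is_zero(self):
        w2, w3 = _panel_waves([FREQ5[1]] * 3, [FREQ5[1]] * 3)
        out = reengagement_score(w2, w3)
        assert out.loc[0, "reengagement"] == 0

    def test_sign_convention(self):
        # wave-2 total 3, wave-3 total 7 -> +4 (re-engagement)
        w2, w3 = _panel_waves([FREQ5[1], FREQ5[1], FREQ5[1]], [FREQ5[3], FREQ5[3], FREQ5[1]])
        assert reengagement_score(w2, w3).loc[0, "reengagement"] == 4
        # reversed: more engagement in wave 2 than wave 3 -> negative
        assert reengagement_score(w3, w2).loc[0, "reengagement"] == -4

    def test_missing_item_gives_missing_score(self):
        w2, w3 = _panel_waves([FREQ5[1]] * 3, [FREQ5[1]] * 3)
        w3.loc[0, COMPLIANCE_ITEMS[2]] = pd.NA
        out = reengagement_score(w2, w3)
        assert pd.isna(out.loc[0, "reengagement"])
        # per-activity differences still emitted for answered items
        assert out.loc[0, f"delta_{COMPLIANCE_ITEMS[0]}"] == 0


class TestRiskRecode:
    def test_floor_and_ceiling_codes(self):
        df = pd.DataFrame(
            {
                "risk_likelihood": ["very unlikely", "very likely"],
                "risk_control": ["no control", "complete control"],
                "risk_severity": ["not at all severe", "extremely severe"],
            }
        ).astype("string")
        out = recode_risk_perception(df)
        assert out.iloc[0].tolist() == [1, 1, 1]
        assert out.iloc[1].tolist() == [5, 5, 5]

    def test_monotone_in_level_order(self, big_panel):
        w2 = big_panel[0].head(200)
        out = recode_risk_perception(w2)
        assert out.notna().all().all()
        assert out.isin(range(1, 6)).all().all()
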