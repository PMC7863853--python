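import numpy as np
import pandas as pd
import pytest

from worry19 import ModelSpec, fit_model, model_report, pca_block_score, significance_stars


@pytest.fixture(scope="module")
def analysis_frame(small_panel):
    from worry19 import classify_table
    from worry19.pipeline import _model_frame

    wave2, _, _ = small_panel
    return _model_frame(classify_table(wave2))


class TestPcaBlockScore:
    def test_rank_one_block_equals_standardized_item(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        block = pd.DataFrame({"a": x, "b": 2 * x + 3})
        scores = pca_block_score(block, "demo")
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(scores, z, atol=1e-10)

    def test_scores_are_standardized(self):
        rng = np.random.default_rng(1)
        block = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        s = pca_block_score(block)
        assert abs(s.mean()) < 1e-6
        assert abs(s.var(ddof=1) - 1) < 1e-6

    def test_sign_flip_equivariance(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(100, 1))
        block = pd.DataFrame(base + 0.3 * rng.normal(size=(100, 3)), columns=list("abc"))
        s = pca_block_score(block)
        assert np.allclose(pca_block_score(-block), -s, atol=1e-10)

    def test_orthogonal_items_first_component_explains_one_over_k(self):
        rng = np.random.default_rng(3)
        k, n = 5, 20_000
        Z = rng.normal(size=(n, k))
        Zs = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        eigvals = np.linalg.svd(Zs, compute_uv=False) ** 2 / (n - 1)
        assert eigvals[0] / eigvals.sum() == pytest.approx(1 / k, abs=0.02)

    def test_zero_variance_item_is_error(self):
        block = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="zero-variance.*b"):
            pca_block_score(block, "blk")


class TestFitModel:
    def test_multinomial_probabilities_and_reference(self, analysis_frame):
        spec = ModelSpec(
            family="multinomial_logit",
            outcome="worry_group",
            terms=["had_covid_bin", "impact_score"],
            reference_category="UNWORRIED",
        )
        res = fit_model(spec, analysis_frame)
        assert set(res.table["outcome_category"]) == {"FUNCTIONAL", "DYSFUNCTIONAL"}
        assert (res.table["estimate"] > 0).all()
        assert (res.table["ci_low"] <= res.table["ci_high"]).all()
        assert res.n <= len(analysis_frame)

    def test_reference_switch_consistency(self, analysis_frame):
        terms = ["had_covid_bin", "impact_score"]
        rU = fit_model(
            ModelSpec("multinomial_logit", "worry_group", terms, reference_category="UNWORRIED"),
            analysis_frame,
        )
        rD = fit_model(
            ModelSpec("multinomial_logit", "worry_group", terms, reference_category="DYSFUNCTIONAL"),
            analysis_frame,
        )
        tU = rU.table.set_index(["outcome_category", "term"])["estimate"]
        tD = rD.table.set_index(["outcome_category", "term"])["estimate"]
        for term in terms:
            direct = tU[("FUNCTIONAL", term)]
            derived = tD[("FUNCTIONAL", term)] / tD[("UNWORRIED", term)]
            assert direct == pytest.approx(derived, abs=1e-6)

    def test_negative_binomial_reports_theta_and_ratios(self, analysis_frame):
        spec = ModelSpec(
            family="negative_binomial",
            outcome="emotion_score_num",
            terms=["C(worry_group, Treatment('UNWORRIED'))"],
        )
        res = fit_model(spec, analysis_frame)
        assert res.theta is not None and res.theta > 0
        assert (res.table["estimate"] > 0).all()

    def test_poisson_and_nb_agree_when_dispersion_vanishes(self):
        rng = np.random.default_rng(8)
        n = 20_000
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.3 * x))
        df = pd.DataFrame({"y": y.astype(float), "x": x})
        pois = fit_model(ModelSpec("poisson", "y", ["x"]), df)
        nb = fit_model(ModelSpec("negative_binomial", "y", ["x"]), df)
        for term in ("Intercept", "x"):
            b_p = pois.table.set_index("term").loc[term, "estimate"]
            b_nb = np.log(nb.table.set_index("term").loc[term, "estimate"])
            assert b_p == pytest.approx(b_nb, abs=1e-4)

    def test_linear_model_recovers_slope(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=2000)
        y = 2.0 + 1.5 * x + rng.normal(scale=0.5, size=2000)
        res = fit_model(ModelSpec("linear", "y", ["x"]), pd.DataFrame({"x": x, "y": y}))
        assert res.table.set_index("term").loc["x", "estimate"] == pytest.approx(1.5, abs=0.05)

    def test_listwise_deletion_reports_reduced_n(self, analysis_frame):
        df = analysis_frame.copy()
        df.loc[df.index[:25], "impact_score"] = np.nan
        res = fit_model(
            ModelSpec("linear", "emotion_score_num", ["impact_score"]), df
        )
        assert res.n == df["emotion_score_num"].notna().sum() - 25

    def test_rank_deficient_design_names_aliased_terms(self, analysis_frame):
        df = analysis_frame.copy()
        df["impact_copy"] = df["impact_score"]
        with pytest.raises(ValueError, match="aliased"):
            fit_model(ModelSpec("linear", "emotion_score_num", ["impact_score", "impact_copy"]), df)

    def test_weighted_fits_supported_only_for_glm_families(self, analysis_frame):
        w = pd.Series(1.0, index=analysis_frame.index)
        with pytest.raises(NotImplementedError):
            fit_model(
                ModelSpec("multinomial_logit", "worry_group", ["impact_score"], reference_category="UNWORRIED"),
                analysis_frame,
                weights=w,
            )
        res = fit_model(ModelSpec("linear", "emotion_score_num", ["impact_score"]), analysis_frame, weights=w)
        unw = fit_model(ModelSpec("linear", "emotion_score_num", ["impact_score"]), analysis_frame)
        assert np.allclose(res.table["estimate"], unw.table["estimate"])


class TestReporting:
    @pytest.mark.parametrize(
        "p, stars",
        [(0.0005, "***"), (0.004, "**"), (0.03, "*"), (0.05, ""), (0.2, "")],
    )
    def test_star_thresholds_are_strict(self, p, stars):
        assert significance_stars(p) == stars

    def test_empty_report(self):
        rep = model_report([])
        assert rep.empty

    def test_report_stacks_models(self, analysis_frame):
        res = fit_model(ModelSpec("linear", "emotion_score_num", ["impact_score"]), analysis_frame)
        rep = model_report([res])
        assert {"model", "term", "estimate", "stars"} <= set(rep.columns)
        assert len(rep) == 2  # intercept + slope
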