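"""Association models over the classified panel.

Four families, mirroring the study's reporting conventions:

* ``multinomial_logit`` — group membership vs a reference group; estimates
  reported as relative-risk ratios (exponentiated coefficients).
* ``negative_binomial`` — emotion-score counts; exponentiated coefficients
  (multiplicative effects on the mean) plus the dispersion theta = 1/alpha.
* ``poisson`` — non-compliance counts; raw coefficients with 95% CIs.
* ``linear`` — change scores; raw OLS coefficients.

Estimation is delegated to statsmodels; this module owns the contracts:
reference categories, reporting scale, listwise deletion with reported n,
convergence and rank-deficiency diagnostics, and the principal-component
scoring of attitudinal covariate blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf

FAMILIES = ("multinomial_logit", "negative_binomial", "poisson", "linear")


class ConvergenceError(RuntimeError):
    """Raised when an estimator fails to converge (e.g. separation)."""


@dataclass
class ModelSpec:
    """Declarative model description.

    ``terms`` are patsy right-hand-side terms (may include ``C(x,
    Treatment('ref'))`` encodings and ``:``/``*`` interactions).
    ``reference_category`` applies to the multinomial outcome only.
    """

    family: str
    outcome: str
    terms: Sequence[str]
    reference_category: Optional[str] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "multinomial_logit" and not self.reference_category:
            raise ValueError("multinomial_logit requires a reference_category")

    @property
    def formula(self) -> str:
        return f"{self.outcome} ~ {' + '.join(self.terms)}"


@dataclass
class ModelResult:
    spec: ModelSpec
    table: pd.DataFrame  # term[, outcome_category], estimate, se, p, ci_low, ci_high
    n: int
    aic: float
    theta: Optional[float] = None  # NB dispersion (1/alpha)
    log_likelihood: Optional[float] = None


def _check_rank(X, names: Optional[Sequence[str]] = None) -> None:
    arr = np.asarray(X, dtype=float)
    if names is None:
        names = list(X.columns) if hasattr(X, "columns") else [str(j) for j in range(arr.shape[1])]
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name columns whose removal does not reduce rank (aliased terms)
        aliased = []
        for j in range(arr.shape[1]):
            keep = [i for i in range(arr.shape[1]) if i != j]
            if np.linalg.matrix_rank(arr[:, keep]) == rank:
                aliased.append(names[j])
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def fit_model(spec: ModelSpec, data: pd.DataFrame, weights: Optional[pd.Series] = None) -> ModelResult:
    """Fit one model with listwise deletion and report on the published scale.

    Multinomial and negative-binomial estimates are exponentiated (relative-risk
    ratios / mean multipliers) with exponentiated 95% CIs; standard errors stay
    on the coefficient (log) scale, matching the reporting convention. Poisson
    and linear results are raw coefficients.
    """
    df = data.copy()
    exponentiate = spec.family in ("multinomial_logit", "negative_binomial")

    if spec.family == "multinomial_logit":
        if weights is not None:
            raise NotImplementedError("weighted multinomial fits are not supported")
        cats = [spec.reference_category] + sorted(
            c for c in df[spec.outcome].dropna().unique() if c != spec.reference_category
        )
        if spec.reference_category not in set(df[spec.outcome].dropna()):
            raise ValueError(f"reference category {spec.reference_category!r} absent from outcome")
        df["_outcome_code"] = df[spec.outcome].map({c: i for i, c in enumerate(cats)})
        y, X = patsy.dmatrices(
            f"_outcome_code ~ {' + '.join(spec.terms)}", df, return_type="dataframe"
        )
        _check_rank(X)
        model = sm.MNLogit(y, X)
        res = model.fit(disp=0, maxiter=500)
        if not res.mle_retvals.get("converged", True):
            raise ConvergenceError(f"multinomial fit did not converge: {res.mle_retvals}")
        rows = []
        z975 = 1.959963984540054
        for j, cat in enumerate(cats[1:]):
            params = res.params.iloc[:, j]
            bse = res.bse.iloc[:, j]
            pvals = res.pvalues.iloc[:, j]
            for term in X.columns:
                rows.append(
                    {
                        "outcome_category": cat,
                        "term": term,
                        "estimate": float(np.exp(params[term])),
                        "se": float(bse[term]),
                        "p": float(pvals[term]),
                        "ci_low": float(np.exp(params[term] - z975 * bse[term])),
                        "ci_high": float(np.exp(params[term] + z975 * bse[term])),
                    }
                )
        table = pd.DataFrame(rows)
        fitted = np.asarray(res.predict())
        assert np.allclose(fitted.sum(axis=1), 1.0, atol=1e-10)
        return ModelResult(
            spec=spec, table=table, n=int(res.nobs), aic=float(res.aic), log_likelihood=float(res.llf)
        )

    if spec.family == "negative_binomial":
        if weights is not None:
            raise NotImplementedError("weighted negative-binomial fits are not supported")
        model = smf.negativebinomial(spec.formula, df)
        _check_rank(model.exog, names=model.exog_names[: model.exog.shape[1]])
        with warnings.catch_warnings():
            # convergence and boundary-Hessian conditions are checked and
            # handled explicitly below
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=500)
        if not res.mle_retvals.get("converged", True):
            # BFGS line searches can stall exactly at the optimum when the
            # dispersion sits near its boundary; a vanishing gradient means
            # the fit is fine. Otherwise retry with a derivative-free pass.
            grad = np.abs(np.asarray(res.mle_retvals.get("gopt", [np.inf]))).max()
            if grad > 1e-4:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(start_params=res.params, method="nm", maxiter=5000, disp=0)
                if not res.mle_retvals.get("converged", True):
                    raise ConvergenceError(
                        f"negative-binomial fit did not converge: {res.mle_retvals}"
                    )
        alpha = float(res.params["alpha"])
        theta = np.inf if alpha <= 0 else 1.0 / alpha
        mean_terms = [t for t in res.params.index if t != "alpha"]
        params, bse, pvalues = res.params, res.bse, res.pvalues
        ci = res.conf_int()
        if np.isnan(np.asarray(bse[mean_terms], dtype=float)).any():
            # joint Hessian is singular when the dispersion sits at its
            # boundary; condition on the estimated dispersion for the SEs
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glm = sm.GLM(
                    model.endog,
                    model.exog,
                    family=sm.families.NegativeBinomial(alpha=max(alpha, 1e-8)),
                ).fit()
            params = pd.Series(glm.params, index=mean_terms)
            params["alpha"] = alpha
            bse = pd.Series(glm.bse, index=mean_terms)
            pvalues = pd.Series(glm.pvalues, index=mean_terms)
            ci = pd.DataFrame(np.asarray(glm.conf_int()), index=mean_terms, columns=[0, 1])
        rows = []
        for term in mean_terms:
            rows.append(
                {
                    "term": term,
                    "estimate": float(np.exp(params[term])),
                    "se": float(bse[term]),
                    "p": float(pvalues[term]),
                    "ci_low": float(np.exp(ci.loc[term, 0])),
                    "ci_high": float(np.exp(ci.loc[term, 1])),
                }
            )
        return ModelResult(
            spec=spec,
            table=pd.DataFrame(rows),
            n=int(res.nobs),
            aic=float(res.aic),
            theta=theta,
            log_likelihood=float(res.llf),
        )

    # poisson / linear: raw coefficients
    if spec.family == "poisson":
        y, X = patsy.dmatrices(spec.formula, df, return_type="dataframe")
        _check_rank(X)
        freq = None
        if weights is not None:
            freq = np.asarray(weights.loc[X.index], dtype=float)
        model = sm.GLM(y, X, family=sm.families.Poisson(), freq_weights=freq)
        res = model.fit()
        if not res.converged:
            raise ConvergenceError("poisson fit did not converge")
    else:  # linear
        y, X = patsy.dmatrices(spec.formula, df, return_type="dataframe")
        _check_rank(X)
        if weights is not None:
            res = sm.WLS(y, X, weights=np.asarray(weights.loc[X.index], dtype=float)).fit()
        else:
            res = sm.OLS(y, X).fit()

    ci = res.conf_int()
    params = np.asarray(res.params).ravel()
    bse = np.asarray(res.bse).ravel()
    pvals = np.asarray(res.pvalues).ravel()
    ci_arr = np.asarray(ci)
    table = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": params,
            "se": bse,
            "p": pvals,
            "ci_low": ci_arr[:, 0],
            "ci_high": ci_arr[:, 1],
        }
    )
    return ModelResult(
        spec=spec,
        table=table,
        n=int(res.nobs),
        aic=float(res.aic),
        log_likelihood=float(res.llf) if hasattr(res, "llf") else None,
    )


# --------------------------------------------------------------------------
# Principal-component block scores
# --------------------------------------------------------------------------


def pca_block_score(items: pd.DataFrame, block_name: str = "") -> pd.Series:
    """First-principal-component score of a standardized item block.

    Items are z-scored (ddof=1); the first right singular vector gives the
    loadings; the sign is oriented so the mean loading is positive (higher
    score = more of the named construct for positively keyed blocks); scores
    are re-standardized to mean 0, variance 1 (ddof=1).
    """
    X = items.astype(float)
    if X.shape[1] < 2:
        raise ValueError("a component block needs at least 2 items")
    if X.isna().any().any():
        raise ValueError("component scores require complete cases")
    sd = X.std(ddof=1)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance item(s) in block {block_name or '<unnamed>'}: {zero_var}")
    Z = (X - X.mean()) / sd
    _, _, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    loadings = vt[0]
    if loadings.mean() < 0 or (loadings.mean() == 0 and loadings[np.nonzero(loadings)[0][0]] < 0):
        loadings = -loadings
    raw = Z.to_numpy() @ loadings
    scores = (raw - raw.mean()) / raw.std(ddof=1)
    return pd.Series(scores, index=items.index, name=block_name or "component_score")


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------


def significance_stars(p: float) -> str:
    """Strict thresholds: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def model_report(results: Sequence[ModelResult]) -> pd.DataFrame:
    """Stacked report table with significance stars for all fitted models."""
    frames = []
    for r in results:
        t = r.table.copy()
        t.insert(0, "model", r.spec.name or r.spec.family)
        t.insert(1, "family", r.spec.family)
        t["stars"] = t["p"].map(significance_stars)
        t["n"] = r.n
        t["aic"] = r.aic
        if r.theta is not None:
            t["theta"] = r.theta
        frames.append(t)
    if not frames:
        return pd.DataFrame(
            columns=["model", "family", "term", "estimate", "se", "p", "ci_low", "ci_high", "stars", "n", "aic"]
        )
    return pd.concat(frames, ignore_index=True)
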