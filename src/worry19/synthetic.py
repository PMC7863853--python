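"""Synthetic two-wave panel generator and the printed-cross-tab fixture.

``generate`` draws a latent worry group per respondent (wave 2 from the
marginal group proportions via a multinomial-logit model on previous COVID
experience; wave 3 through a row-stochastic transition kernel with completely
random attrition) and then fills every questionnaire item *inside the cell
that defines the group*, so the full classifier recovers the latent group with
zero error by construction. Emotion items come from a one-factor latent-normal
model whose means are solved analytically so group-level expected scores equal
the configured baseline times the group multipliers after discretization to
the five-point scale.

``fixture_from_crosstabs`` is a deterministic 1091-row unit-record table whose
worry/precaution/quality-of-life cross-tabs reproduce the published wave-2
cell counts exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .survey_io import (
    AGE_BANDS,
    AGREE5,
    CITIES,
    COMPLIANCE_ITEMS,
    COVARIATE_BLOCKS,
    EMOTION_ITEMS,
    ETHNICITIES,
    EXPERIENCE_ITEMS,
    FREQ5,
    GENDERS,
    INTENSITY5,
    LIKERT5,
    POSITIVE_EMOTIONS,
    default_codebook,
)

GROUPS = ("UNWORRIED", "FUNCTIONAL", "DYSFUNCTIONAL")


def default_transition_kernel(
    stay: float = 0.71, proportions=(401 / 1091, 203 / 1091, 487 / 1091)
) -> np.ndarray:
    """Row-stochastic kernel with constant diagonal; off-diagonal mass split
    proportionally to the marginal shares of the destination groups."""
    p = np.asarray(proportions, dtype=float)
    K = np.zeros((3, 3))
    for i in range(3):
        K[i, i] = stay
        others = [j for j in range(3) if j != i]
        w = p[others] / p[others].sum()
        for j, wj in zip(others, w):
            K[i, j] = (1 - stay) * wj
    return K


@dataclass
class GeneratorConfig:
    """All distributional parameters of the synthetic panel.

    Defaults encode the study conditions: wave sizes 1100/1019, group shares
    0.37/0.19/0.45, transition-kernel diagonal 0.71, Table-4 relative-risk
    ratios for previous-experience effects on group membership, and Table-5
    emotion-score baseline/multipliers with item correlation targeting an
    internal consistency of roughly 0.88.
    """

    n_wave2: int = 1100
    attrition_rate: float = 1.0 - 1019.0 / 1100.0
    seed: int = 0
    # exact published group counts 401/203/487 over 1091 (prints as 37/19/45%)
    group_proportions: tuple[float, float, float] = (401 / 1091, 203 / 1091, 487 / 1091)
    transition_stay: float = 0.71
    transition_kernel: Optional[np.ndarray] = None  # built from stay prob if None

    # previous experience
    experience_marginals: tuple[float, ...] = (0.14, 0.10, 0.06, 0.004, 0.05, 0.02, 0.03, 0.03)
    had_covid_rate: float = 0.10
    suspected_covid_rate: float = 0.15
    # multinomial-logit effects on group membership, (functional, dysfunctional) vs unworried
    rrr_had_covid: tuple[float, float] = (2.439, 1.012)
    rrr_impact: tuple[float, float] = (0.979, 1.465)

    # emotion score model (six 1-5 items; multipliers in group order U/F/D)
    emotion_baseline_mean: float = 14.312
    emotion_group_multipliers: tuple[float, float, float] = (1.0, 0.913, 1.164)
    emotion_item_sd: float = 0.8
    emotion_interitem_corr: float = 0.62

    # risk-perception latent means (likelihood, control, severity) per group:
    # unworried lowest likelihood/severity and highest control, dysfunctional
    # the reverse, functional in between
    risk_means: dict = field(
        default_factory=lambda: {
            "UNWORRIED": (2.2, 3.4, 2.6),
            "FUNCTIONAL": (2.6, 3.2, 2.9),
            "DYSFUNCTIONAL": (3.1, 2.7, 3.4),
        }
    )
    risk_sd: float = 1.0

    # compliance behaviours: Binomial(4, p) frequency per item per wave
    compliance_p_wave2: float = 0.15
    compliance_p_wave3: float = 0.35

    # dysfunctional sub-cell mix (no precautions, not safer, safer missing,
    # precautions+safer but QoL reduced), from the printed cell counts
    dysfunctional_cells: tuple[float, float, float, float] = (34 / 487, 5 / 487, 10 / 487, 438 / 487)

    # demographics
    age_margins: tuple[float, ...] = (0.20, 0.45, 0.28, 0.07)
    gender_margins: tuple[float, ...] = (0.50, 0.50)
    ethnicity_margins: tuple[float, ...] = (0.82, 0.18)
    keyworker_rate: float = 0.30
    city_margins: tuple[float, ...] = (0.095,) * 10 + (0.05,)

    # switch off every group effect (type-I-error / null simulations)
    null_effects: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.group_proportions, dtype=float)
        if abs(p.sum() - 1) > 1e-9 or (p < 0).any():
            raise ValueError("group_proportions must be nonnegative and sum to 1")
        K = self.kernel()
        if K.shape != (3, 3) or not np.allclose(K.sum(axis=1), 1, atol=1e-9) or (K < 0).any():
            raise ValueError("transition kernel rows must be nonnegative and sum to 1")
        for name in ("attrition_rate", "had_covid_rate", "suspected_covid_rate", "keyworker_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(not 0 <= m <= 1 for m in self.experience_marginals):
            raise ValueError("experience_marginals must be probabilities")

    def kernel(self) -> np.ndarray:
        if self.transition_kernel is not None:
            return np.asarray(self.transition_kernel, dtype=float)
        return default_transition_kernel(self.transition_stay, self.group_proportions)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["transition_kernel"] = self.kernel().tolist()
        return d


# --------------------------------------------------------------------------
# Latent-normal discretization helpers
# --------------------------------------------------------------------------


def _discretized_mean(mu: float, sd: float, k: int = 5) -> float:
    """E[clip(round(N(mu, sd)), 1, k)] in closed form."""
    cuts = np.arange(1, k) + 0.5  # 1.5 .. k-0.5
    cdf = norm.cdf((cuts - mu) / sd)
    probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    return float(np.dot(np.arange(1, k + 1), probs))


def solve_latent_mean(target_mean: float, sd: float, k: int = 5) -> float:
    """Latent mean whose discretized five-point mean equals ``target_mean``."""
    if not 1 < target_mean < k:
        raise ValueError(f"target mean {target_mean} outside (1, {k})")
    return brentq(lambda m: _discretized_mean(m, sd, k) - target_mean, -4.0, k + 4.0, xtol=1e-12)


def _discretize(z: np.ndarray, k: int = 5) -> np.ndarray:
    return np.clip(np.rint(z), 1, k).astype(int)


def _levels_from_codes(codes: np.ndarray, scale: tuple[str, ...]) -> np.ndarray:
    return np.asarray(scale, dtype=object)[codes - 1]


# --------------------------------------------------------------------------
# Group-membership model
# --------------------------------------------------------------------------


def _calibrate_intercepts(
    had_covid: np.ndarray, impact: np.ndarray, cfg: GeneratorConfig, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Solve multinomial-logit intercepts so mean membership probabilities
    match the configured group proportions on the realized covariates.

    Returns (intercepts[2], probs n x 3).
    """
    if cfg.null_effects:
        bF = bD = np.zeros(2)
        beta_h = beta_m = np.zeros(2)
    else:
        beta_h = np.log(np.asarray(cfg.rrr_had_covid))
        beta_m = np.log(np.asarray(cfg.rrr_impact))
    targets = np.asarray(cfg.group_proportions, dtype=float)
    a = np.zeros(2)  # intercepts for F, D
    X = np.column_stack([had_covid, impact]).astype(float)
    eta_fd = X @ np.column_stack([beta_h, beta_m]).T  # n x 2
    for _ in range(max_iter):
        u = np.column_stack([np.zeros(len(X)), eta_fd + a])
        u -= u.max(axis=1, keepdims=True)
        p = np.exp(u)
        p /= p.sum(axis=1, keepdims=True)
        mean_p = p.mean(axis=0)
        step = np.log(targets[1:] / mean_p[1:])
        a += step
        if np.abs(step).max() < 1e-12:
            break
    u = np.column_stack([np.zeros(len(X)), eta_fd + a])
    u -= u.max(axis=1, keepdims=True)
    p = np.exp(u)
    p /= p.sum(axis=1, keepdims=True)
    return a, p


# --------------------------------------------------------------------------
# Item filling
# --------------------------------------------------------------------------


def _draw_levels(rng, n: int, scale: tuple[str, ...], probs) -> np.ndarray:
    idx = rng.choice(len(scale), size=n, p=np.asarray(probs, dtype=float))
    return np.asarray(scale, dtype=object)[idx]


def _emotion_items(rng, groups: np.ndarray, cfg: GeneratorConfig) -> dict[str, np.ndarray]:
    """Six correlated 1-5 items; group means calibrated after discretization."""
    mult = (1.0, 1.0, 1.0) if cfg.null_effects else cfg.emotion_group_multipliers
    mus = {
        g: solve_latent_mean(cfg.emotion_baseline_mean * m / 6.0, cfg.emotion_item_sd)
        for g, m in zip(GROUPS, mult)
    }
    n = len(groups)
    mu = np.array([mus[g] for g in groups])
    r = cfg.emotion_interitem_corr
    f = rng.standard_normal(n)
    out = {}
    for item in EMOTION_ITEMS:
        e = rng.standard_normal(n)
        z = mu + cfg.emotion_item_sd * (np.sqrt(r) * f + np.sqrt(1 - r) * e)
        codes = _discretize(z)
        # stored answers are raw scale labels; positive items are asked
        # positively, so their raw level is the reverse of the "bad" code
        if item in POSITIVE_EMOTIONS:
            codes = 6 - codes
        out[item] = _levels_from_codes(codes, LIKERT5)
    return out


def _worry_block(rng, groups: np.ndarray, cfg: GeneratorConfig) -> dict[str, np.ndarray]:
    """Worry, precaution and quality-of-life answers inside group-defining cells."""
    n = len(groups)
    low, high = LIKERT5[:2], LIKERT5[2:]
    positive = LIKERT5[2:]  # feel-safer positive levels

    worried = np.where(groups == "UNWORRIED", "no", "yes").astype(object)
    freq = np.empty(n, dtype=object)
    intens = np.empty(n, dtype=object)
    prec = np.empty(n, dtype=object)
    safer = np.empty(n, dtype=object)
    qw = np.empty(n, dtype=object)
    qp = np.empty(n, dtype=object)

    u = groups == "UNWORRIED"
    nu = int(u.sum())
    if nu:
        freq[u] = FREQ5[0]
        intens[u] = INTENSITY5[0]
        prec[u] = np.where(rng.random(nu) < 0.9, "yes", "no")
        safer[u] = _draw_levels(rng, nu, LIKERT5, (0.05, 0.10, 0.30, 0.35, 0.20))
        safer[u & (prec == "no")] = pd.NA
        qw[u] = _draw_levels(rng, nu, LIKERT5, (0.80, 0.15, 0.05, 0.0, 0.0))
        qp[u] = _draw_levels(rng, nu, LIKERT5, (0.55, 0.25, 0.12, 0.06, 0.02))
        qp[u & (prec == "no")] = pd.NA

    w = ~u
    nw = int(w.sum())
    if nw:
        # worried respondents: reported frequency/intensity mix
        freq[w] = _draw_levels(rng, nw, FREQ5, (0.0, 0.35, 0.25, 0.19, 0.21))
        intens[w] = _draw_levels(rng, nw, INTENSITY5, (0.0, 0.10, 0.32, 0.38, 0.20))

    f = groups == "FUNCTIONAL"
    nf = int(f.sum())
    if nf:
        prec[f] = "yes"
        safer[f] = _draw_levels(rng, nf, positive, (0.30, 0.40, 0.30))
        qw[f] = _draw_levels(rng, nf, low, (0.6, 0.4))
        qp[f] = _draw_levels(rng, nf, low, (0.6, 0.4))

    d = groups == "DYSFUNCTIONAL"
    nd = int(d.sum())
    if nd:
        cell = rng.choice(4, size=nd, p=np.asarray(cfg.dysfunctional_cells))
        dprec = np.empty(nd, dtype=object)
        dsafer = np.empty(nd, dtype=object)
        dqw = np.empty(nd, dtype=object)
        dqp = np.empty(nd, dtype=object)
        # cell 0: takes no precautions (QoL free; mostly reduced)
        m = cell == 0
        dprec[m] = "no"
        dsafer[m] = pd.NA
        dqw[m] = _draw_levels(rng, int(m.sum()), LIKERT5, (0.05, 0.05, 0.35, 0.35, 0.20))
        dqp[m] = pd.NA
        # cell 1: precautions but does not feel safer
        m = cell == 1
        dprec[m] = "yes"
        dsafer[m] = _draw_levels(rng, int(m.sum()), low, (0.5, 0.5))
        dqw[m] = _draw_levels(rng, int(m.sum()), LIKERT5, (0.10, 0.15, 0.35, 0.25, 0.15))
        dqp[m] = _draw_levels(rng, int(m.sum()), LIKERT5, (0.20, 0.25, 0.30, 0.15, 0.10))
        # cell 2: precautions, feel-safer unanswered; QoL reduced
        m = cell == 2
        dprec[m] = "yes"
        dsafer[m] = pd.NA
        dqw[m] = _draw_levels(rng, int(m.sum()), high, (0.5, 0.3, 0.2))
        dqp[m] = _draw_levels(rng, int(m.sum()), LIKERT5, (0.2, 0.3, 0.3, 0.1, 0.1))
        # cell 3: precautions + safer, but QoL reduced by worry and/or precautions
        m = cell == 3
        nm = int(m.sum())
        dprec[m] = "yes"
        dsafer[m] = _draw_levels(rng, nm, positive, (0.35, 0.40, 0.25))
        pattern = rng.choice(3, size=nm, p=(0.5, 0.25, 0.25))  # both, worry-only, precaution-only
        qw_m = np.empty(nm, dtype=object)
        qp_m = np.empty(nm, dtype=object)
        hi = lambda size: _draw_levels(rng, size, high, (0.45, 0.35, 0.20))
        lo = lambda size: _draw_levels(rng, size, low, (0.5, 0.5))
        for pat in range(3):
            sel = pattern == pat
            ns = int(sel.sum())
            qw_m[sel] = hi(ns) if pat in (0, 1) else lo(ns)
            qp_m[sel] = hi(ns) if pat in (0, 2) else lo(ns)
        dqw[m] = qw_m
        dqp[m] = qp_m
        prec[d], safer[d], qw[d], qp[d] = dprec, dsafer, dqw, dqp

    return {
        "worried": worried,
        "worry_frequency": freq,
        "worry_intensity": intens,
        "takes_precautions": prec,
        "feel_safer": safer,
        "qol_worry": qw,
        "qol_precautions": qp,
    }


def _risk_block(rng, groups: np.ndarray, cfg: GeneratorConfig) -> dict[str, np.ndarray]:
    cb = default_codebook()
    out = {}
    if cfg.null_effects:
        means = {g: (2.6, 3.1, 3.0) for g in GROUPS}
    else:
        means = cfg.risk_means
    mu = np.array([means[g] for g in groups])  # n x 3
    for j, item in enumerate(("risk_likelihood", "risk_control", "risk_severity")):
        z = mu[:, j] + cfg.risk_sd * rng.standard_normal(len(groups))
        out[item] = _levels_from_codes(_discretize(z), cb.levels(item))
    return out


def _covariate_blocks(rng, n: int) -> dict[str, np.ndarray]:
    out = {"knowledge": _levels_from_codes(_discretize(3.5 + 0.9 * rng.standard_normal(n)), AGREE5)}
    for _, items in COVARIATE_BLOCKS.items():
        f = rng.standard_normal(n)
        for item in items:
            z = 3.0 + 0.8 * (0.7 * f + 0.3 * rng.standard_normal(n))
            out[item] = _levels_from_codes(_discretize(z), AGREE5)
    return out


def _compliance_block(rng, n: int, p: float) -> dict[str, np.ndarray]:
    return {
        item: _levels_from_codes(rng.binomial(4, p, size=n) + 1, FREQ5)
        for item in COMPLIANCE_ITEMS
    }


def _wave_frame(rid, wave, demo, exp, worry, emo, risk, cov, comp) -> pd.DataFrame:
    cb = default_codebook()
    df = pd.DataFrame({"respondent_id": rid})
    df["wave"] = wave
    for block in (worry, exp, emo, comp, risk, cov, demo):
        for k, v in block.items():
            df[k] = v
    # column order follows the codebook for stable serialization
    ordered = ["respondent_id", "wave"] + [c for c in cb.item_names() if c in df.columns and c != "respondent_id"]
    df = df[ordered]
    for c in df.columns:
        if c != "wave":
            df[c] = df[c].astype("string")
    return df


def generate(cfg: GeneratorConfig, seed: Optional[int] = None):
    """Generate (wave-2 table, wave-3 table, truth record).

    The truth record stores the latent group per respondent and wave, the
    calibrated multinomial intercepts, and the full parameter set.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_wave2
    cb = default_codebook()
    if n == 0:
        cols = ["respondent_id", "wave"] + [c for c in cb.item_names() if c != "respondent_id"]
        empty = pd.DataFrame({c: pd.Series(dtype="string" if c != "wave" else int) for c in cols})
        truth = {"params": cfg.to_jsonable(), "group_w2": {}, "group_w3": {}, "intercepts": [0.0, 0.0]}
        return empty, empty.copy(), truth

    rid = np.array([f"r{i:05d}" for i in range(n)], dtype=object)

    # exogenous covariates
    exp = {
        item: np.where(rng.random(n) < p, "yes", "no").astype(object)
        for item, p in zip(EXPERIENCE_ITEMS, cfg.experience_marginals)
    }
    had = (rng.random(n) < cfg.had_covid_rate).astype(int)
    exp_block = dict(exp)
    exp_block["had_covid"] = np.where(had == 1, "yes", "no").astype(object)
    exp_block["suspected_covid"] = np.where(
        rng.random(n) < cfg.suspected_covid_rate, "yes", "no"
    ).astype(object)
    impact = np.sum([exp[i] == "yes" for i in EXPERIENCE_ITEMS], axis=0).astype(int)

    # latent groups
    intercepts, probs = _calibrate_intercepts(had, impact, cfg)
    draw = rng.random(n)
    cum = probs.cumsum(axis=1)
    g2_idx = (draw[:, None] > cum).sum(axis=1)
    K = cfg.kernel()
    g3_idx = np.array([rng.choice(3, p=K[i]) for i in g2_idx])
    groups2 = np.asarray(GROUPS, dtype=object)[g2_idx]
    groups3 = np.asarray(GROUPS, dtype=object)[g3_idx]

    demo = {
        "age_band": _draw_levels(rng, n, AGE_BANDS, cfg.age_margins),
        "gender": _draw_levels(rng, n, GENDERS, cfg.gender_margins),
        "ethnicity": _draw_levels(rng, n, ETHNICITIES, cfg.ethnicity_margins),
        "keyworker": np.where(rng.random(n) < cfg.keyworker_rate, "yes", "no").astype(object),
        "city": _draw_levels(rng, n, CITIES, cfg.city_margins),
    }

    wave2 = _wave_frame(
        rid,
        2,
        demo,
        exp_block,
        _worry_block(rng, groups2, cfg),
        _emotion_items(rng, groups2, cfg),
        _risk_block(rng, groups2, cfg),
        _covariate_blocks(rng, n),
        _compliance_block(rng, n, cfg.compliance_p_wave2),
    )

    # attrition: completely at random
    retained = rng.random(n) >= cfg.attrition_rate
    wave3_full = _wave_frame(
        rid,
        3,
        demo,
        exp_block,
        _worry_block(rng, groups3, cfg),
        _emotion_items(rng, groups3, cfg),
        _risk_block(rng, groups3, cfg),
        _covariate_blocks(rng, n),
        _compliance_block(rng, n, cfg.compliance_p_wave3),
    )
    wave3 = wave3_full.loc[retained].reset_index(drop=True)

    truth = {
        "params": cfg.to_jsonable(),
        "intercepts": intercepts.tolist(),
        "group_w2": dict(zip(rid.tolist(), groups2.tolist())),
        "group_w3": dict(zip(rid[retained].tolist(), groups3[retained].tolist())),
        "n_wave3": int(retained.sum()),
    }
    return wave2, wave3, truth


# --------------------------------------------------------------------------
# Deterministic fixture reconstructed from the printed cross-tabs
# --------------------------------------------------------------------------

FIXTURE_COUNTS = {
    "unworried": 401,
    "worried": 690,
    "no_precautions": 34,
    "precautions_feels_safer": 641,
    "precautions_not_safer": 5,
    "safer_missing": 10,
    "functional_cell": 203,
    "qol_none_or_little_total": 206,
    "qol_some_or_strong_total": 484,
    "dysfunctional": 487,
}


def fixture_from_crosstabs() -> pd.DataFrame:
    """Deterministic 1091-row wave-2 table matching the published cell counts.

    Worried rows: 34 take no precautions (3 of them with no quality-of-life
    impact), 641 take precautions and feel safer (203 unaffected = the
    functional cell, 438 affected), 5 take precautions without feeling safer,
    and 10 left the feel-safer item unanswered (placed in the affected
    column). Items outside the classification battery carry fixed valid
    levels and cycling demographics.
    """
    low0, low1 = LIKERT5[0], LIKERT5[1]
    high = LIKERT5[3]  # "quite a bit"
    rows: list[dict] = []

    def add(n, worried, prec, safer, qw, qp):
        for _ in range(n):
            rows.append(
                {
                    "worried": worried,
                    "takes_precautions": prec,
                    "feel_safer": safer,
                    "qol_worry": qw,
                    "qol_precautions": qp,
                }
            )

    add(401, "no", "yes", high, low0, low1)  # unworried (other answers irrelevant)
    add(3, "yes", "no", pd.NA, low0, low0)  # no precautions, QoL unaffected
    add(31, "yes", "no", pd.NA, high, low0)  # no precautions, QoL reduced
    add(203, "yes", "yes", high, low0, low1)  # functional cell
    add(438, "yes", "yes", high, high, low1)  # safer but QoL reduced
    add(5, "yes", "yes", low1, high, low1)  # precautions, not safer
    add(10, "yes", "yes", pd.NA, high, low1)  # feel-safer unanswered

    df = pd.DataFrame(rows)
    n = len(df)
    df.insert(0, "respondent_id", [f"w2-{i:04d}" for i in range(n)])
    df.insert(1, "wave", 2)
    idx = np.arange(n)
    df["worry_frequency"] = np.where(df["worried"] == "yes", FREQ5[1], FREQ5[0])
    df["worry_intensity"] = np.where(df["worried"] == "yes", INTENSITY5[3], INTENSITY5[0])
    df["had_covid"] = "no"
    df["suspected_covid"] = "no"
    for item in EXPERIENCE_ITEMS:
        df[item] = "no"
    for j, item in enumerate(EMOTION_ITEMS):
        df[item] = np.asarray(LIKERT5, dtype=object)[(idx * (j + 1) + j) % 5]
    for item in COMPLIANCE_ITEMS:
        df[item] = FREQ5[0]
    cb = default_codebook()
    for item in ("risk_likelihood", "risk_control", "risk_severity"):
        df[item] = cb.levels(item)[2]
    df["knowledge"] = AGREE5[3]
    for items in COVARIATE_BLOCKS.values():
        for item in items:
            df[item] = AGREE5[3]
    df["age_band"] = np.asarray(AGE_BANDS, dtype=object)[idx % 4]
    df["gender"] = np.asarray(GENDERS, dtype=object)[idx % 2]
    df["ethnicity"] = np.where(idx % 6 == 0, ETHNICITIES[1], ETHNICITIES[0])
    df["keyworker"] = np.where(idx % 3 == 0, "yes", "no")
    df["city"] = np.asarray(CITIES[:10], dtype=object)[idx % 10]
    ordered = ["respondent_id", "wave"] + [
        c for c in cb.item_names() if c in df.columns and c != "respondent_id"
    ]
    df = df[ordered]
    for c in df.columns:
        if c != "wave":
            df[c] = df[c].astype("string")
    return df
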