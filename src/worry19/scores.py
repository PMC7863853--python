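"""Derived indices: COVID-impact score, emotion recodes and summative score
with Cronbach's alpha, re-engagement change score, and risk-perception codes.

The impact and re-engagement scores are formative indices — plain sums of
indicators, not reflections of a latent construct — so no reliability is
attached to them. The emotion score is summative over six 1-5 items with the
three positively keyed items (happiness, worthwhile, satisfied) reverse-coded
so that higher always means a worse emotional outcome.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .survey_io import (
    COMPLIANCE_ITEMS,
    EMOTION_ITEMS,
    EXPERIENCE_ITEMS,
    FREQ5,
    LIKERT5,
    NEGATIVE_EMOTIONS,
    POSITIVE_EMOTIONS,
    RISK_ITEMS,
    Codebook,
    default_codebook,
)

# --------------------------------------------------------------------------
# COVID-impact score (0-8 adversity count)
# --------------------------------------------------------------------------


def covid_impact_score(df: pd.DataFrame) -> pd.DataFrame:
    """Sum the eight binary adversity indicators per respondent.

    Missing indicators count as 0 (no reported adversity); rows with any
    missing indicator are flagged. ``had_covid`` / ``suspected_covid`` are
    deliberately not included — they enter models as separate predictors.
    """
    yes = pd.DataFrame({c: (df[c].astype("string") == "yes") for c in EXPERIENCE_ITEMS})
    any_missing = pd.concat([df[c].astype("string").isna() for c in EXPERIENCE_ITEMS], axis=1).any(axis=1)
    value = yes.fillna(False).sum(axis=1).astype(int)
    return pd.DataFrame(
        {"impact_score": value, "impact_any_missing": any_missing}, index=df.index
    )


# --------------------------------------------------------------------------
# Emotion recodes, summative score and reliability
# --------------------------------------------------------------------------


def recode_emotion_binary(values: pd.Series, item_name: str) -> pd.Series:
    """Collapse one emotion item to a yes/no bad-outcome indicator.

    Negative emotions (anxiety, anger, loneliness): 'no' iff 'not at all',
    everyone else 'yes'. Positive items (happiness, worthwhile, satisfied):
    'yes' iff 'not at all' (never felt happy / worthwhile / satisfied), so
    'yes' always marks the bad outcome.
    """
    v = values.astype("string")
    at_floor = v == LIKERT5[0]
    if item_name in NEGATIVE_EMOTIONS:
        out = at_floor.map({True: "no", False: "yes"})
    elif item_name in POSITIVE_EMOTIONS:
        out = at_floor.map({True: "yes", False: "no"})
    else:
        raise ValueError(f"unknown emotion item {item_name!r}")
    return out.where(~v.isna(), pd.NA).astype("string")


def emotion_item_codes(df: pd.DataFrame) -> pd.DataFrame:
    """Integer-code the six emotion items 1-5, higher = worse.

    Positive items are reverse-keyed ('not at all' happy -> 5). Applying the
    reverse key twice restores the raw coding.
    """
    level_code = {lvl: i + 1 for i, lvl in enumerate(LIKERT5)}
    out = {}
    for item in EMOTION_ITEMS:
        codes = df[item].astype("string").map(level_code).astype("Int64")
        if item in POSITIVE_EMOTIONS:
            codes = 6 - codes
        out[item] = codes
    return pd.DataFrame(out, index=df.index)


def emotion_score(df: pd.DataFrame) -> pd.Series:
    """Summative emotion score in [6, 30]; missing if any item is missing."""
    codes = emotion_item_codes(df)
    total = codes.sum(axis=1, skipna=False).astype("Int64")
    total.name = "emotion_score"
    return total


def cronbach_alpha(item_matrix) -> float:
    """Internal-consistency alpha: (k/(k-1)) * (1 - sum(item var) / total var).

    Variances use ddof=1. Raises if the total-score variance is zero (alpha
    undefined).
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 and k >= 2")
    if np.isnan(X).any():
        raise ValueError("item matrix must have no missing rows")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return (k / (k - 1)) * (1 - item_vars.sum() / total_var)


# --------------------------------------------------------------------------
# Re-engagement change score
# --------------------------------------------------------------------------


def compliance_codes(df: pd.DataFrame) -> pd.DataFrame:
    """Frequency levels of the three behaviour items coded 0..4."""
    level_code = {lvl: i for i, lvl in enumerate(FREQ5)}
    return pd.DataFrame(
        {c: df[c].astype("string").map(level_code).astype("Int64") for c in COMPLIANCE_ITEMS},
        index=df.index,
    )


def noncompliance_count(df: pd.DataFrame) -> pd.Series:
    """Total behaviour frequency (0-12); a non-compliance count in wave 2."""
    total = compliance_codes(df).sum(axis=1, skipna=False).astype("Int64")
    total.name = "noncompliance_count"
    return total


def reengagement_score(wave2: pd.DataFrame, wave3: pd.DataFrame) -> pd.DataFrame:
    """Wave-3 minus wave-2 behaviour totals per linked respondent.

    0 means no change; negative means more engagement in wave 2 than wave 3
    (less activity after easing); positive means re-engagement. Missing any
    activity item in either wave makes the score missing. Per-activity
    differences are emitted alongside the total.
    """
    w2 = wave2.set_index("respondent_id")
    w3 = wave3.set_index("respondent_id")
    common = w2.index.intersection(w3.index)
    c2 = compliance_codes(w2.loc[common])
    c3 = compliance_codes(w3.loc[common])
    out = pd.DataFrame(index=common)
    out.index.name = "respondent_id"
    for item in COMPLIANCE_ITEMS:
        out[f"delta_{item}"] = (c3[item] - c2[item]).astype("Int64")
    out["w2_total"] = c2.sum(axis=1, skipna=False).astype("Int64")
    out["w3_total"] = c3.sum(axis=1, skipna=False).astype("Int64")
    out["reengagement"] = (out["w3_total"] - out["w2_total"]).astype("Int64")
    return out.reset_index()


# --------------------------------------------------------------------------
# Risk-perception recodes
# --------------------------------------------------------------------------


def recode_risk_perception(df: pd.DataFrame, codebook: Codebook | None = None) -> pd.DataFrame:
    """Integer-code the risk triad 1..5 in codebook level order.

    Higher = more likely to catch the virus / more control over catching it /
    more severe expected consequences. Any monotone relabelling of the levels
    leaves the rank order of the codes unchanged.
    """
    cb = codebook or default_codebook()
    out = {}
    for item in RISK_ITEMS:
        level_code = {lvl: i + 1 for i, lvl in enumerate(cb.levels(item))}
        out[item] = df[item].astype("string").map(level_code).astype("Int64")
    return pd.DataFrame(out, index=df.index)
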