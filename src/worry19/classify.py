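"""Three-group worry classification: unworried, functional, dysfunctional.

The scheme distinguishes worry that motivates beneficial precaution (functional)
from worry that damages quality of life (dysfunctional):

* **UNWORRIED** — reported no worry about catching COVID-19 in the reference
  period; precautionary behaviour and its effects are irrelevant.
* **FUNCTIONAL** — worried, takes precautions, the precautions make the
  respondent feel safer, and quality of life is reduced by *neither* the worry
  nor the precautions (at most "a little" on both impact items).
* **DYSFUNCTIONAL** — worried, and any of: takes no precautions; precautions do
  not make them feel safer (or the feel-safer item is unanswered); quality of
  life has some or strong impact from worry and/or precautions.
* **UNCLASSIFIABLE** — the worry item itself is missing (and, under the
  ``unclassifiable`` missing-QoL policy, worried respondents with missing
  quality-of-life answers).

A simplified two-way variant ignores precautions entirely and splits the
worried on whether worry alone reduces quality of life.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .survey_io import LIKERT5


class WorryGroup(str, enum.Enum):
    UNWORRIED = "UNWORRIED"
    FUNCTIONAL = "FUNCTIONAL"
    DYSFUNCTIONAL = "DYSFUNCTIONAL"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"


class Rationale(str, enum.Enum):
    """Which rule assigned the label — makes cell membership auditable."""

    NOT_WORRIED = "NOT_WORRIED"
    ALL_THREE_CONDITIONS = "ALL_THREE_CONDITIONS"
    NO_PRECAUTIONS = "NO_PRECAUTIONS"
    NOT_SAFER = "NOT_SAFER"
    SAFER_MISSING = "SAFER_MISSING"
    QOL_REDUCED = "QOL_REDUCED"
    QOL_MISSING = "QOL_MISSING"
    WORRY_MISSING = "WORRY_MISSING"
    QOL_WORRY_LOW = "QOL_WORRY_LOW"  # simplified scheme only


#: fixed group order used for tables, transition matrices and serialization
GROUP_ORDER = (WorryGroup.UNWORRIED, WorryGroup.FUNCTIONAL, WorryGroup.DYSFUNCTIONAL)
GROUP_LABELS = tuple(g.value for g in GROUP_ORDER)

#: combined quality-of-life impact outcomes
QOL_NONE_OR_LITTLE = "none_or_little_both"
QOL_SOME_OR_STRONG = "some_or_strong_either"
QOL_MISSING = "missing"


@dataclass(frozen=True)
class DichotomyConfig:
    """Cut points for the two dichotomies the classifier depends on.

    ``feel_safer_positive_levels`` must be upward-closed and ``qol_low_levels``
    downward-closed in the five-point extent scale, so each dichotomy is a
    single ordinal cut.
    """

    feel_safer_positive_levels: tuple[str, ...] = ("moderately", "quite a bit", "very much")
    qol_low_levels: tuple[str, ...] = ("not at all", "a little")
    missing_qol_policy: str = "dysfunctional"  # or "unclassifiable"
    scale: tuple[str, ...] = LIKERT5

    def __post_init__(self) -> None:
        order = {lvl: i for i, lvl in enumerate(self.scale)}
        pos = sorted(order[x] for x in self.feel_safer_positive_levels)
        if not pos or pos != list(range(pos[0], len(self.scale))):
            raise ValueError("feel_safer_positive_levels must be a nonempty upward-closed set")
        low = sorted(order[x] for x in self.qol_low_levels)
        if low != list(range(len(low))):
            raise ValueError("qol_low_levels must be downward-closed")
        if self.missing_qol_policy not in ("dysfunctional", "unclassifiable"):
            raise ValueError("missing_qol_policy must be 'dysfunctional' or 'unclassifiable'")


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value)


def combined_qol_impact(qol_worry, qol_precautions, cfg: DichotomyConfig = DichotomyConfig()) -> str:
    """Dichotomise the joint quality-of-life impact of worry and precautions.

    ``none_or_little_both`` iff both items are in the low set;
    ``some_or_strong_either`` iff at least one item is outside it (a single
    high answer decides regardless of the other being missing); ``missing``
    iff an item is missing and the other does not already decide.
    """
    low = set(cfg.qol_low_levels)
    w_miss, p_miss = _is_missing(qol_worry), _is_missing(qol_precautions)
    w_high = (not w_miss) and qol_worry not in low
    p_high = (not p_miss) and qol_precautions not in low
    if w_high or p_high:
        return QOL_SOME_OR_STRONG
    if w_miss or p_miss:
        return QOL_MISSING
    return QOL_NONE_OR_LITTLE


def classify_full(record: Mapping, cfg: DichotomyConfig = DichotomyConfig()) -> tuple[WorryGroup, Rationale]:
    """Classify one respondent-wave under the full three-group scheme."""
    worried = record.get("worried")
    if _is_missing(worried):
        return WorryGroup.UNCLASSIFIABLE, Rationale.WORRY_MISSING
    if worried == "no":
        return WorryGroup.UNWORRIED, Rationale.NOT_WORRIED
    # worried = yes: precautionary pathway
    precautions = record.get("takes_precautions")
    if _is_missing(precautions) or precautions == "no":
        return WorryGroup.DYSFUNCTIONAL, Rationale.NO_PRECAUTIONS
    safer = record.get("feel_safer")
    if _is_missing(safer):
        return WorryGroup.DYSFUNCTIONAL, Rationale.SAFER_MISSING
    if safer not in cfg.feel_safer_positive_levels:
        return WorryGroup.DYSFUNCTIONAL, Rationale.NOT_SAFER
    qol = combined_qol_impact(record.get("qol_worry"), record.get("qol_precautions"), cfg)
    if qol == QOL_SOME_OR_STRONG:
        return WorryGroup.DYSFUNCTIONAL, Rationale.QOL_REDUCED
    if qol == QOL_MISSING:
        if cfg.missing_qol_policy == "unclassifiable":
            return WorryGroup.UNCLASSIFIABLE, Rationale.QOL_MISSING
        return WorryGroup.DYSFUNCTIONAL, Rationale.QOL_MISSING
    return WorryGroup.FUNCTIONAL, Rationale.ALL_THREE_CONDITIONS


def classify_simplified(record: Mapping, cfg: DichotomyConfig = DichotomyConfig()) -> tuple[WorryGroup, Rationale]:
    """Two-way split of the worried on worry's own quality-of-life impact.

    Precaution items are ignored entirely, for surveys that cannot carry the
    full follow-up battery.
    """
    worried = record.get("worried")
    if _is_missing(worried):
        return WorryGroup.UNCLASSIFIABLE, Rationale.WORRY_MISSING
    if worried == "no":
        return WorryGroup.UNWORRIED, Rationale.NOT_WORRIED
    qol_worry = record.get("qol_worry")
    if _is_missing(qol_worry):
        if cfg.missing_qol_policy == "unclassifiable":
            return WorryGroup.UNCLASSIFIABLE, Rationale.QOL_MISSING
        return WorryGroup.DYSFUNCTIONAL, Rationale.QOL_MISSING
    if qol_worry in cfg.qol_low_levels:
        return WorryGroup.FUNCTIONAL, Rationale.QOL_WORRY_LOW
    return WorryGroup.DYSFUNCTIONAL, Rationale.QOL_REDUCED


def classify_table(
    df: pd.DataFrame, cfg: DichotomyConfig = DichotomyConfig(), scheme: str = "full"
) -> pd.DataFrame:
    """Append ``worry_group`` and ``rationale_code`` columns (vectorised)."""
    if scheme not in ("full", "simplified"):
        raise ValueError("scheme must be 'full' or 'simplified'")
    n = len(df)
    group = np.full(n, WorryGroup.UNCLASSIFIABLE.value, dtype=object)
    rationale = np.full(n, Rationale.WORRY_MISSING.value, dtype=object)

    worried = df["worried"].astype("string")
    w_missing = worried.isna().to_numpy()
    w_no = (worried == "no").fillna(False).to_numpy()
    w_yes = (worried == "yes").fillna(False).to_numpy()
    group[w_no] = WorryGroup.UNWORRIED.value
    rationale[w_no] = Rationale.NOT_WORRIED.value

    low = list(cfg.qol_low_levels)
    qw = df["qol_worry"].astype("string")
    qp = df["qol_precautions"].astype("string") if "qol_precautions" in df else pd.Series(pd.NA, index=df.index, dtype="string")
    qw_high = (~qw.isna() & ~qw.isin(low)).to_numpy()
    qp_high = (~qp.isna() & ~qp.isin(low)).to_numpy()
    qol_some = qw_high | qp_high
    qol_missing = ~qol_some & (qw.isna() | qp.isna()).to_numpy()

    if scheme == "simplified":
        dys = w_yes & qw_high
        fun = w_yes & ~qw_high & ~qw.isna().to_numpy()
        miss = w_yes & qw.isna().to_numpy()
        group[dys] = WorryGroup.DYSFUNCTIONAL.value
        rationale[dys] = Rationale.QOL_REDUCED.value
        group[fun] = WorryGroup.FUNCTIONAL.value
        rationale[fun] = Rationale.QOL_WORRY_LOW.value
        if cfg.missing_qol_policy == "dysfunctional":
            group[miss] = WorryGroup.DYSFUNCTIONAL.value
        rationale[miss] = Rationale.QOL_MISSING.value
    else:
        prec = df["takes_precautions"].astype("string")
        safer = df["feel_safer"].astype("string") if "feel_safer" in df else pd.Series(pd.NA, index=df.index, dtype="string")
        no_prec = (prec.isna() | (prec == "no")).to_numpy()
        safer_missing = (~prec.isna() & (prec == "yes")).to_numpy() & safer.isna().to_numpy()
        not_safer = (
            (prec == "yes").fillna(False).to_numpy()
            & ~safer.isna().to_numpy()
            & ~safer.isin(list(cfg.feel_safer_positive_levels)).to_numpy()
        )
        # precedence mirrors the scalar rule order
        remaining = w_yes.copy()
        for mask, rat in (
            (no_prec, Rationale.NO_PRECAUTIONS),
            (safer_missing, Rationale.SAFER_MISSING),
            (not_safer, Rationale.NOT_SAFER),
        ):
            hit = remaining & mask
            group[hit] = WorryGroup.DYSFUNCTIONAL.value
            rationale[hit] = rat.value
            remaining &= ~mask
        hit = remaining & qol_some
        group[hit] = WorryGroup.DYSFUNCTIONAL.value
        rationale[hit] = Rationale.QOL_REDUCED.value
        remaining &= ~qol_some
        hit = remaining & qol_missing
        if cfg.missing_qol_policy == "dysfunctional":
            group[hit] = WorryGroup.DYSFUNCTIONAL.value
        rationale[hit] = Rationale.QOL_MISSING.value
        remaining &= ~qol_missing
        group[remaining] = WorryGroup.FUNCTIONAL.value
        rationale[remaining] = Rationale.ALL_THREE_CONDITIONS.value

    out = df.copy()
    out["worry_group"] = group
    out["rationale_code"] = rationale
    return out


# --------------------------------------------------------------------------
# Group tables (machine twins of the published cross-tabs)
# --------------------------------------------------------------------------

PRECAUTION_CELLS = (
    "no_precautions",
    "precautions_feels_safer",
    "precautions_not_safer",
    "safer_missing",
)


def precaution_cell(df: pd.DataFrame, cfg: DichotomyConfig = DichotomyConfig()) -> pd.Series:
    """Assign each row to one of the four precaution/feel-safer cells."""
    prec = df["takes_precautions"].astype("string")
    safer = df["feel_safer"].astype("string")
    out = pd.Series("no_precautions", index=df.index, dtype=object)
    takes = (prec == "yes").fillna(False)
    out[takes & safer.isna()] = "safer_missing"
    out[takes & safer.isin(list(cfg.feel_safer_positive_levels))] = "precautions_feels_safer"
    out[takes & ~safer.isna() & ~safer.isin(list(cfg.feel_safer_positive_levels))] = "precautions_not_safer"
    return out


@dataclass
class GroupTables:
    """Worry/precaution/quality-of-life cross-tabs with group assignment."""

    worry_by_precaution: pd.DataFrame  # Table 1 layout
    precaution_by_qol: pd.DataFrame  # Table 2 layout, functional cell flagged
    group_counts: pd.DataFrame  # Table 3 layout
    n_classified: int = 0
    weighted: Optional["GroupTables"] = None


def build_group_tables(
    df: pd.DataFrame,
    cfg: DichotomyConfig = DichotomyConfig(),
    weights: Optional[pd.Series] = None,
) -> GroupTables:
    """Cross-tabulate worry, precautionary activity and quality-of-life impact.

    Reproduces the three published table layouts: worried × precaution cell
    (row percentages), precaution cell × combined QoL impact among the worried
    (with the functional cell flagged), and the group count/percentage table.
    """
    classified = classify_table(df, cfg, scheme="full")
    w = weights if weights is not None else pd.Series(1.0, index=df.index)

    worried = classified["worried"].astype("string")
    is_worried = (worried == "yes").fillna(False)
    cells = precaution_cell(classified, cfg)

    # Table 1 layout: worried row split over precaution cells
    t1_rows = []
    unworried_n = float(w[(worried == "no").fillna(False)].sum())
    t1_rows.append({"worry": "unworried", "n": unworried_n, **{c: np.nan for c in PRECAUTION_CELLS}})
    worried_n = float(w[is_worried].sum())
    row = {"worry": "worried", "n": worried_n}
    for c in PRECAUTION_CELLS:
        row[c] = float(w[is_worried & (cells == c)].sum())
    t1_rows.append(row)
    table1 = pd.DataFrame(t1_rows)
    for c in PRECAUTION_CELLS:
        table1[f"{c}_pct"] = 100 * table1[c] / table1["n"]

    # Table 2 layout: precaution rows × combined QoL impact, worried only
    qol = classified.apply(
        lambda r: combined_qol_impact(r.get("qol_worry"), r.get("qol_precautions"), cfg), axis=1
    )
    row_map = {
        "precautions_feels_safer": "took_precautions_felt_safer",
        "no_precautions": "no_precautions_or_not_safer",
        "precautions_not_safer": "no_precautions_or_not_safer",
        "safer_missing": "did_not_answer_safer",
    }
    t2_index = ["took_precautions_felt_safer", "no_precautions_or_not_safer", "did_not_answer_safer"]
    t2_cols = [QOL_NONE_OR_LITTLE, QOL_SOME_OR_STRONG, QOL_MISSING]
    table2 = pd.DataFrame(0.0, index=pd.Index(t2_index, name="precaution_row"), columns=t2_cols)
    sub = pd.DataFrame({"row": cells[is_worried].map(row_map), "qol": qol[is_worried], "w": w[is_worried]})
    agg = sub.groupby(["row", "qol"])["w"].sum()
    for (r, q), v in agg.items():
        table2.loc[r, q] = float(v)
    table2["total"] = table2.sum(axis=1)
    table2 = table2.reset_index()
    table2["functional_cell"] = (table2["precaution_row"] == "took_precautions_felt_safer").map(
        {True: QOL_NONE_OR_LITTLE, False: ""}
    )

    # Table 3 layout: group counts and percentages
    grp = classified["worry_group"]
    classifiable = grp != WorryGroup.UNCLASSIFIABLE.value
    n_classified = float(w[classifiable].sum())
    rows = []
    for g in GROUP_LABELS:
        gn = float(w[grp == g].sum())
        rows.append({"worry_group": g, "n": gn, "pct": 100 * gn / n_classified if n_classified else np.nan})
    table3 = pd.DataFrame(rows)

    result = GroupTables(
        worry_by_precaution=table1,
        precaution_by_qol=table2,
        group_counts=table3,
        n_classified=int(round(n_classified)) if weights is None else n_classified,
    )
    if weights is not None:
        pass  # already weighted
    return result


def build_group_tables_with_weights(
    df: pd.DataFrame, cfg: DichotomyConfig, weights: pd.Series
) -> GroupTables:
    """Unweighted tables with a weighted twin attached."""
    tables = build_group_tables(df, cfg)
    tables.weighted = build_group_tables(df, cfg, weights=weights)
    return tables
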