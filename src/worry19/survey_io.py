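"""Unit-record data model: codebook, wave-table I/O, and panel linkage.

A survey wave is held as a :class:`pandas.DataFrame` of string-coded answers
(one row per respondent, one column per codebook item, ``pd.NA`` for missing).
The :class:`Codebook` defines the item inventory — names, types, ordered level
labels — and is the single source of truth for validation and for ordinal
integer coding downstream.

The default codebook is a reconstruction: the study's questionnaire wording is
not public, so canonical snake_case item names and level labels are defined
here, with an alias map for renaming external columns.
"""

from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger("worry19")

# --------------------------------------------------------------------------
# Level-label vocabularies
# --------------------------------------------------------------------------

BINARY = ("no", "yes")
#: extent scale used for quality-of-life impact, feel-safer and emotion items
LIKERT5 = ("not at all", "a little", "moderately", "quite a bit", "very much")
#: agreement scale used for attitudinal covariate blocks
AGREE5 = ("strongly disagree", "disagree", "neither", "agree", "strongly agree")
#: three-week frequency scale (worry frequency, compliance behaviours)
FREQ5 = ("not at all", "once or twice", "3-5 times", "6-10 times", "more than 10 times")
INTENSITY5 = (
    "not at all worried",
    "not very worried",
    "a little worried",
    "fairly worried",
    "very worried",
)
LIKELIHOOD5 = ("very unlikely", "unlikely", "neither", "likely", "very likely")
CONTROL5 = ("no control", "a little control", "some control", "a lot of control", "complete control")
SEVERITY5 = ("not at all severe", "a little severe", "moderately severe", "very severe", "extremely severe")

AGE_BANDS = ("16-24", "25-44", "45-64", "65+")
GENDERS = ("male", "female")
ETHNICITIES = ("White", "BAME")
CITIES = (
    "Birmingham",
    "Cardiff",
    "Edinburgh",
    "Glasgow",
    "Leeds",
    "Liverpool",
    "London",
    "Manchester",
    "Newcastle",
    "Sheffield",
    "none of these",
)

#: the eight binary adversity indicators summed into the COVID-impact score
EXPERIENCE_ITEMS = (
    "exp_self_work_loss",
    "exp_household_job_loss",
    "exp_unable_pay_bills",
    "exp_unable_access_food",
    "exp_unable_access_medication",
    "exp_lost_accommodation",
    "exp_close_hospitalised",
    "exp_close_died",
)

#: six wellbeing items; the last three are positively keyed (reverse-coded downstream)
EMOTION_ITEMS = (
    "emo_anxiety",
    "emo_anger",
    "emo_loneliness",
    "emo_happiness",
    "emo_worthwhile",
    "emo_satisfied",
)
NEGATIVE_EMOTIONS = ("emo_anxiety", "emo_anger", "emo_loneliness")
POSITIVE_EMOTIONS = ("emo_happiness", "emo_worthwhile", "emo_satisfied")

#: three lockdown-behaviour items (in breach in wave 2, permitted in wave 3)
COMPLIANCE_ITEMS = ("comp_socialised", "comp_exercise_relax", "comp_travelled")

RISK_ITEMS = ("risk_likelihood", "risk_control", "risk_severity")

#: attitudinal covariate blocks scored by principal components downstream
COVARIATE_BLOCKS: dict[str, tuple[str, ...]] = {
    "deterrence": ("deter_socialise", "deter_exercise", "deter_travel"),
    "legal_legitimacy": ("legit_law_duty", "legit_law_align"),
    "police_legitimacy": ("legit_police_duty", "legit_police_align"),
    "social_norms": ("norm_personal", "norm_community"),
    "expressive_law": ("expressive_right", "expressive_clarify", "expressive_message"),
}

#: columns the classifier cannot run without
MANDATORY_COLUMNS = ("worried", "takes_precautions", "qol_worry", "qol_precautions")

VALID_WAVES = (2, 3)


# --------------------------------------------------------------------------
# Codebook
# --------------------------------------------------------------------------

ITEM_TYPES = ("binary", "likert5", "count", "categorical", "freetext-skip")


@dataclass(frozen=True)
class ItemSpec:
    """One questionnaire item: its type and ordered level labels."""

    name: str
    item_type: str
    levels: tuple[str, ...] = ()
    waves: tuple[int, ...] = VALID_WAVES

    def __post_init__(self) -> None:
        if self.item_type not in ITEM_TYPES:
            raise ValueError(f"unknown item_type {self.item_type!r} for {self.name}")
        if self.item_type == "likert5" and len(self.levels) != 5:
            raise ValueError(f"likert5 item {self.name} must have exactly 5 levels")
        if self.item_type == "binary" and len(self.levels) != 2:
            raise ValueError(f"binary item {self.name} must have exactly 2 levels")


@dataclass
class Codebook:
    """Item inventory plus missing-value codes and column aliases."""

    items: dict[str, ItemSpec]
    missing_codes: tuple[str, ...] = ("",)
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, spec in self.items.items():
            if name != spec.name:
                raise ValueError(f"item key {name!r} != spec name {spec.name!r}")
            overlap = set(self.missing_codes) & set(spec.levels)
            if overlap:
                raise ValueError(f"missing codes {overlap} collide with levels of {name}")

    def item_names(self) -> tuple[str, ...]:
        return tuple(self.items)

    def levels(self, item: str) -> tuple[str, ...]:
        return self.items[item].levels

    def level_codes(self, item: str) -> dict[str, int]:
        """Ordinal integer code for each level, 0..k-1 in codebook order."""
        return {lvl: i for i, lvl in enumerate(self.items[item].levels)}

    def to_yaml(self, path: str | pathlib.Path) -> None:
        payload = {
            "missing_codes": list(self.missing_codes),
            "aliases": dict(self.aliases),
            "items": [
                {
                    "name": s.name,
                    "item_type": s.item_type,
                    "levels": list(s.levels),
                    "waves": list(s.waves),
                }
                for s in self.items.values()
            ],
        }
        pathlib.Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "Codebook":
        payload = yaml.safe_load(pathlib.Path(path).read_text())
        items = {
            d["name"]: ItemSpec(
                name=d["name"],
                item_type=d["item_type"],
                levels=tuple(d.get("levels", ())),
                waves=tuple(d.get("waves", VALID_WAVES)),
            )
            for d in payload["items"]
        }
        return cls(
            items=items,
            missing_codes=tuple(payload.get("missing_codes", ("",))),
            aliases=dict(payload.get("aliases", {})),
        )


def _binary(name: str, waves: tuple[int, ...] = VALID_WAVES) -> ItemSpec:
    return ItemSpec(name, "binary", BINARY, waves)


def _likert(name: str, levels: tuple[str, ...] = LIKERT5, waves: tuple[int, ...] = VALID_WAVES) -> ItemSpec:
    return ItemSpec(name, "likert5", levels, waves)


def default_codebook() -> Codebook:
    """Reconstructed codebook covering every item the pipeline consumes."""
    specs: list[ItemSpec] = [
        ItemSpec("respondent_id", "freetext-skip"),
        # worry block
        _binary("worried"),
        _likert("worry_frequency", FREQ5),
        _likert("worry_intensity", INTENSITY5),
        _likert("qol_worry"),
        # precaution block
        _binary("takes_precautions"),
        _likert("feel_safer"),
        _likert("qol_precautions"),
        # previous experience
        _binary("had_covid"),
        _binary("suspected_covid"),
        *[_binary(n) for n in EXPERIENCE_ITEMS],
        # emotions / life evaluation
        *[_likert(n) for n in EMOTION_ITEMS],
        # compliance behaviours
        *[_likert(n, FREQ5) for n in COMPLIANCE_ITEMS],
        # risk perception triad
        _likert("risk_likelihood", LIKELIHOOD5),
        _likert("risk_control", CONTROL5),
        _likert("risk_severity", SEVERITY5),
        # attitudinal covariates
        _likert("knowledge", AGREE5),
        *[_likert(n, AGREE5) for block in COVARIATE_BLOCKS.values() for n in block],
        # demographics
        ItemSpec("age_band", "categorical", AGE_BANDS),
        ItemSpec("gender", "categorical", GENDERS),
        ItemSpec("ethnicity", "categorical", ETHNICITIES),
        _binary("keyworker"),
        ItemSpec("city", "categorical", CITIES),
    ]
    return Codebook(items={s.name: s for s in specs})


# --------------------------------------------------------------------------
# Validation and reading
# --------------------------------------------------------------------------


@dataclass
class ValidationReport:
    wave: int
    n_rows: int
    warning_counts: dict[str, int] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)

    @property
    def n_warnings(self) -> int:
        return sum(self.warning_counts.values())


def validate_table(df: pd.DataFrame, codebook: Codebook, wave: int) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate every cell against the codebook.

    Values matching a missing code become ``pd.NA``; values outside an item's
    level set also become ``pd.NA`` and are tallied as warnings. Validation is
    idempotent: a validated table revalidates with zero warnings.
    """
    if wave not in VALID_WAVES:
        raise ValueError(f"unknown wave id {wave!r}; expected one of {VALID_WAVES}")
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing mandatory columns: {', '.join(missing_cols)}")
    if "respondent_id" not in df.columns:
        raise ValueError("missing mandatory columns: respondent_id")
    dupes = df["respondent_id"][df["respondent_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate respondent_id within wave {wave}: {sorted(set(dupes))[:5]}")

    out = df.copy()
    report = ValidationReport(wave=wave, n_rows=len(df))
    missing = set(codebook.missing_codes)
    for col in out.columns:
        spec = codebook.items.get(col)
        if spec is None:
            report.messages.append(f"column {col!r} not in codebook; passed through")
            continue
        if spec.item_type == "freetext-skip" or not spec.levels:
            continue
        vals = out[col].astype("string")
        is_missing = vals.isna() | vals.isin(missing)
        invalid = ~is_missing & ~vals.isin(spec.levels)
        n_bad = int(invalid.sum())
        if n_bad:
            report.warning_counts[col] = n_bad
            logger.warning("wave %d: %d invalid value(s) in %r set to missing", wave, n_bad, col)
        vals = vals.mask(is_missing | invalid, pd.NA)
        out[col] = vals
    return out, report


def read_wave(
    path: str | pathlib.Path, codebook: Codebook, wave: int
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read one wave's CSV and validate it against the codebook."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.rename(columns=codebook.aliases)
    df = df.astype("string")
    if "wave" in df.columns:
        waves_seen = set(df["wave"].dropna().unique())
        if waves_seen - {str(wave)}:
            raise ValueError(f"file {path} contains wave ids {waves_seen}, expected {{{wave}}}")
        df = df.drop(columns=["wave"])
    validated, report = validate_table(df, codebook, wave)
    validated.insert(1, "wave", wave)
    return validated, report


# --------------------------------------------------------------------------
# Panel linkage
# --------------------------------------------------------------------------


@dataclass
class PanelTable:
    """Two linked wave tables keyed by respondent_id."""

    wave2: pd.DataFrame
    wave3: pd.DataFrame
    linkage: pd.DataFrame  # respondent_id, linkage_status

    @property
    def both_waves_ids(self) -> list[str]:
        m = self.linkage["linkage_status"] == "both_waves"
        return self.linkage.loc[m, "respondent_id"].tolist()

    def counts(self) -> dict[str, int]:
        return self.linkage["linkage_status"].value_counts().to_dict()


def link_panel(wave2: pd.DataFrame, wave3: pd.DataFrame) -> PanelTable:
    """Link respondents across waves on respondent_id.

    Respondents present in both waves get ``both_waves``; one-sided respondents
    are retained with ``wave2_only`` / ``wave3_only`` flags.
    """
    for df, w in ((wave2, 2), (wave3, 3)):
        dup = df["respondent_id"][df["respondent_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate respondent_id within wave {w}: {sorted(set(dup))[:5]}")
    ids2, ids3 = set(wave2["respondent_id"]), set(wave3["respondent_id"])
    both = ids2 & ids3
    if not both:
        logger.warning("link_panel: no respondents appear in both waves")
    rows = (
        [(rid, "both_waves") for rid in sorted(both)]
        + [(rid, "wave2_only") for rid in sorted(ids2 - ids3)]
        + [(rid, "wave3_only") for rid in sorted(ids3 - ids2)]
    )
    linkage = pd.DataFrame(rows, columns=["respondent_id", "linkage_status"])
    return PanelTable(wave2=wave2, wave3=wave3, linkage=linkage)


def write_outputs(tables: Mapping[str, pd.DataFrame], outdir: str | pathlib.Path) -> list[pathlib.Path]:
    """Write each table as ``<name>.csv`` with stable column order.

    Output is deterministic: identical tables produce byte-identical files.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, na_rep="")
        written.append(path)
    return written
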