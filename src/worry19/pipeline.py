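"""End-to-end orchestration: simulate/load -> classify -> scores -> weights ->
transitions -> models -> report, with a reproducibility manifest.

A single YAML config drives the run; one top-level seed feeds every source of
randomness. The manifest records the config hash, a checksum for every output
file, per-stage row counts and warnings, so identical config + inputs yield
identical data outputs (manifest timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .classify import DichotomyConfig, build_group_tables, classify_table
from .models import ModelSpec, fit_model, model_report, pca_block_score
from .scores import (
    covid_impact_score,
    cronbach_alpha,
    emotion_item_codes,
    emotion_score,
    noncompliance_count,
    recode_risk_perception,
    reengagement_score,
)
from .survey_io import COVARIATE_BLOCKS, default_codebook, link_panel, read_wave, validate_table, write_outputs
from .synthetic import GeneratorConfig, fixture_from_crosstabs, generate
from .transitions import sankey_table, transitions
from .weighting import MarginTargets, compute_weights, weighted_counts

logger = logging.getLogger("worry19")

_KNOWN_KEYS = {"seed", "output_dir", "input", "classify", "weights", "models", "transitions"}


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dichotomy_config(section: dict) -> DichotomyConfig:
    kwargs = {}
    for key in ("feel_safer_positive_levels", "qol_low_levels"):
        if key in section:
            kwargs[key] = tuple(section[key])
    if "missing_qol_policy" in section:
        kwargs["missing_qol_policy"] = section["missing_qol_policy"]
    return DichotomyConfig(**kwargs)


def validate_config(config: dict) -> None:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    mode = config.get("input", {}).get("mode", "simulate")
    if mode not in ("simulate", "files", "fixture"):
        raise ValueError(f"input.mode must be simulate|files|fixture, got {mode!r}")
    if mode == "files":
        missing = [k for k in ("wave2", "wave3") if k not in config["input"]]
        if missing:
            raise ValueError(f"input.mode=files requires paths: {missing}")
    w = config.get("weights", {})
    if w.get("enabled") and "targets" not in w:
        raise ValueError("stage quota_weighting: weighting requested but no targets supplied")


def _default_model_specs() -> list[ModelSpec]:
    fd = "C(worry_group, Treatment('UNWORRIED'))"
    pc_terms = [f"pc_{b}" for b in COVARIATE_BLOCKS]
    return [
        ModelSpec(
            family="multinomial_logit",
            outcome="worry_group",
            terms=["had_covid_bin", "impact_score"],
            reference_category="UNWORRIED",
            name="experience_to_group",
        ),
        ModelSpec(
            family="negative_binomial",
            outcome="emotion_score_num",
            terms=[fd],
            name="emotion_by_group",
        ),
        ModelSpec(
            family="poisson",
            outcome="noncompliance_num",
            terms=["knowledge_num", *pc_terms, fd],
            name="noncompliance",
        ),
        ModelSpec(
            family="linear",
            outcome="reengagement",
            terms=["had_covid_bin", "impact_score", fd],
            name="reengagement_change",
        ),
    ]


def _model_frame(classified: pd.DataFrame) -> pd.DataFrame:
    """Assemble the analysis frame: scores, recodes and PC block scores."""
    df = classified.copy()
    df["had_covid_bin"] = (df["had_covid"].astype("string") == "yes").astype(int)
    df = pd.concat([df, covid_impact_score(df)], axis=1)
    df["emotion_score_num"] = emotion_score(df).astype("float")
    df["noncompliance_num"] = noncompliance_count(df).astype("float")
    risk = recode_risk_perception(df)
    for c in risk:
        df[f"{c}_num"] = risk[c].astype("float")
    agree_code = {lvl: i + 1 for i, lvl in enumerate(("strongly disagree", "disagree", "neither", "agree", "strongly agree"))}
    df["knowledge_num"] = df["knowledge"].astype("string").map(agree_code).astype("float")
    for block, items in COVARIATE_BLOCKS.items():
        codes = pd.DataFrame({i: df[i].astype("string").map(agree_code) for i in items}).astype(float)
        complete = codes.dropna()
        if len(complete) >= 3 and (complete.std(ddof=1) > 0).all():
            df.loc[complete.index, f"pc_{block}"] = pca_block_score(complete, block)
    return df


def run_pipeline(config: dict | str | pathlib.Path, output_dir: Optional[str] = None) -> dict:
    """Execute all stages in dependency order; returns the run manifest.

    Any stage failure aborts with the stage name; the partial manifest written
    so far is preserved in the exception context.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(pathlib.Path(config).read_text())
    validate_config(config)
    seed = int(config.get("seed", 0))
    outdir = pathlib.Path(output_dir or config.get("output_dir", "worry19_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    codebook = default_codebook()
    cfg = _dichotomy_config(config.get("classify", {}))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "stages": {},
        "outputs": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    stage = "input"
    try:
        mode = config.get("input", {}).get("mode", "simulate")
        if mode == "simulate":
            gen_over = dict(config.get("input", {}).get("generator", {}))
            gen = GeneratorConfig(**gen_over, seed=seed) if "seed" not in gen_over else GeneratorConfig(**gen_over)
            wave2, wave3, truth = generate(gen)
            (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        elif mode == "fixture":
            wave2 = fixture_from_crosstabs()
            wave3 = wave2.iloc[0:0].copy()
        else:
            wave2, rep2 = read_wave(config["input"]["wave2"], codebook, 2)
            wave3, rep3 = read_wave(config["input"]["wave3"], codebook, 3)
            manifest["stages"]["validate"] = {
                "wave2_warnings": rep2.n_warnings,
                "wave3_warnings": rep3.n_warnings,
            }
        stage = "validate"
        wave2, rep2 = validate_table(wave2, codebook, 2)
        manifest["stages"]["input"] = {"wave2_rows": len(wave2), "wave3_rows": len(wave3)}
        if len(wave3):
            wave3, rep3 = validate_table(wave3, codebook, 3)

        stage = "worry_classification"
        w2c = classify_table(wave2, cfg)
        tables = build_group_tables(wave2, cfg)
        out_tables = {
            "wave2_classified": w2c,
            "table1_worry_by_precaution": tables.worry_by_precaution,
            "table2_precaution_by_qol": tables.precaution_by_qol,
            "table3_group_counts": tables.group_counts,
        }
        manifest["stages"]["worry_classification"] = {
            "n_classified": tables.n_classified,
            "group_counts": dict(
                zip(tables.group_counts["worry_group"], tables.group_counts["n"].astype(int))
            ),
        }
        w3c = classify_table(wave3, cfg) if len(wave3) else wave3

        stage = "derived_scores"
        frame2 = _model_frame(w2c)
        score_summary = {
            "impact_mean": float(frame2["impact_score"].mean()),
            "emotion_mean": float(frame2["emotion_score_num"].mean()),
        }
        emo = emotion_item_codes(wave2).dropna()
        if len(emo) >= 2:
            try:
                score_summary["cronbach_alpha"] = float(cronbach_alpha(emo))
            except ValueError:
                score_summary["cronbach_alpha"] = None  # degenerate item matrix
        out_tables["wave2_scores"] = frame2[
            ["respondent_id", "worry_group", "impact_score", "emotion_score_num", "noncompliance_num"]
        ]
        manifest["stages"]["derived_scores"] = score_summary

        stage = "quota_weighting"
        wsec = config.get("weights", {})
        if wsec.get("enabled"):
            targets = MarginTargets(
                margins=wsec["targets"].get("margins", {}),
                cells={tuple(k.split("|")): v for k, v in wsec["targets"].get("cells", {}).items()}
                or None,
                total=wsec["targets"].get("total"),
            )
            weights = compute_weights(wave2, targets, mode=wsec.get("mode", "cell"))
            out_tables["wave2_weights"] = pd.DataFrame(
                {"respondent_id": wave2["respondent_id"], "weight": weights}
            )
            out_tables["weighted_group_counts"] = weighted_counts(w2c, weights, by="worry_group")
            manifest["stages"]["quota_weighting"] = {"weight_total": float(weights.sum())}

        stage = "panel_transitions"
        if len(wave3):
            panel = link_panel(wave2, wave3)
            tm = transitions(panel, cfg)
            out_tables["transition_counts"] = tm.counts.reset_index()
            out_tables["transition_flows"] = sankey_table(tm)
            manifest["stages"]["panel_transitions"] = {
                "n_linked": tm.n_linked,
                "n_excluded": tm.n_excluded,
                "stability_share": tm.stability_share,
            }

        stage = "association_models"
        if config.get("models", {}).get("enabled", mode == "simulate") and len(wave3):
            frame = frame2.copy()
            reeng = reengagement_score(wave2, wave3).set_index("respondent_id")["reengagement"]
            frame = frame.set_index("respondent_id")
            frame["reengagement"] = reeng.astype("float")
            frame = frame.reset_index()
            frame = frame[frame["worry_group"].isin(["UNWORRIED", "FUNCTIONAL", "DYSFUNCTIONAL"])]
            results = [fit_model(spec, frame) for spec in _default_model_specs()]
            out_tables["model_tables"] = model_report(results)
            manifest["stages"]["association_models"] = {
                r.spec.name: {"n": r.n, "aic": r.aic} for r in results
            }

        stage = "write_outputs"
        written = write_outputs(out_tables, outdir)
        for path in written:
            manifest["outputs"][path.name] = _sha256(path)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
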