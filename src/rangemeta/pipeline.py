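"""End-to-end synthesis pipeline: effects -> fits -> averaging -> scenarios.

Chains the stages of the published-analysis workflow on an observation
table (read from CSV or generated synthetically): effect-size construction
with variance recovery and audit, data-sufficiency screens, per-outcome
overall random-effects fits (REML), all-subsets explanatory model sets with
AIC averaging (ML), and the equal-inputs scenario grid with benefit/harm
tallies.  All randomness derives from a single configured seed so stage-wise
and end-to-end runs produce identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import effect_sizes as es
from .meta_model import RandomEffectsSpec, fit_meta_model, report_overall_effect
from .model_averaging import fit_model_set
from .scenarios import (
    DEFAULT_AMOUNTS,
    DEFAULT_CLIMATE_CODE,
    DEFAULT_DAYS,
    DEFAULT_N_CONCENTRATIONS,
    DEFAULT_POLARITY,
    build_scenario_grid,
    predict_scenario,
    rank_scenarios,
    scores_to_frame,
    select_model_set,
    tabulate_benefits_harms,
)
from .io import write_csv
from .synthetic_data import CorpusConfig, generate_corpus, spawn_seed

log = logging.getLogger("rangemeta")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "simulate_observations"]


@dataclass
class PipelineConfig:
    """Settings for one full run; defaults reproduce the published analysis."""

    seed: int = 0
    min_obs_effect: int = 10
    min_experiments_effect: int = 3
    min_obs_explanatory: int = 50
    min_experiments_explanatory: int = 5
    min_experiments_per_zone: int = 3
    importance_cutoff: float = 0.8
    ci_level: float = 0.95
    weighting: str = "unweighted"
    interaction_mode: str = "permissive"
    set_selection_rule: str = "min_aic"
    allow_nonsignificant: bool = False
    scenario_amounts: tuple = DEFAULT_AMOUNTS
    scenario_n_concentrations: tuple = DEFAULT_N_CONCENTRATIONS
    scenario_days: float = DEFAULT_DAYS
    scenario_climate: float = DEFAULT_CLIMATE_CODE
    polarity: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_POLARITY))
    #: candidate moderators for explanatory models (availability rules still apply)
    moderators: tuple = (
        "days_since_application", "amount_applied", "amendment_n",
        "climate_zone", "soil_depth",
    )
    #: outcomes whose models take a measurement-method random effect
    method_re_outcomes: tuple = ()
    #: synthetic corpora to generate when no observation table is supplied
    simulate: tuple = ()  # of CorpusConfig-like dicts

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        outcomes = raw.pop("outcomes", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if outcomes:
            cfg.simulate = tuple(outcomes)
        if cfg.weighting not in ("unweighted", "inverse_variance"):
            raise ValueError(f"unknown weighting {cfg.weighting!r}")
        return cfg


def _corpus_config(spec: dict, seed: int) -> CorpusConfig:
    spec = dict(spec)
    effects = spec.pop("true_moderator_effects", {}) or {}
    parsed = {}
    for key, value in effects.items():
        parsed[tuple(key.split(":")) if ":" in str(key) else key] = float(value)
    rv = spec.get("response_variable", "outcome")
    spec.setdefault("seed", spawn_seed(seed, "simulate", rv))
    return CorpusConfig(true_moderator_effects=parsed, **spec)


def simulate_observations(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Generate the configured synthetic corpora (one per outcome)."""
    tables, truths = [], {}
    for spec in config.simulate:
        corpus_cfg = _corpus_config(dict(spec), config.seed)
        table, truth = generate_corpus(corpus_cfg)
        tables.append(table)
        truths[corpus_cfg.response_variable] = truth
    if not tables:
        raise ValueError("pipeline config declares no synthetic outcomes")
    return pd.concat(tables, ignore_index=True), truths


@dataclass
class ReportBundle:
    """All pipeline outputs for one run."""

    effects: pd.DataFrame
    audit: pd.DataFrame
    sufficiency: pd.DataFrame
    overall: pd.DataFrame
    averaged: dict[str, pd.DataFrame]
    selected_flavor: dict[str, str]
    scenario_report: pd.DataFrame | None
    rankings: dict[str, list] | None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_csv(self.effects, outdir / "effects.csv")
        write_csv(self.audit, outdir / "audit.csv")
        write_csv(self.sufficiency, outdir / "sufficiency.csv")
        write_csv(self.overall, outdir / "overall_effects.csv")
        for outcome, table in self.averaged.items():
            table.to_csv(outdir / f"averaged_{outcome}.csv", float_format="%.17g")
        if self.scenario_report is not None:
            write_csv(self.scenario_report, outdir / "scenarios.csv")


def _moderator_terms(config: PipelineConfig, effects_rv: pd.DataFrame) -> list[str]:
    """Candidate main terms for one outcome, honoring the data-driven rules."""
    terms = []
    for term in config.moderators:
        if term == "climate_zone":
            if es.climate_zones_sufficient(effects_rv, config.min_experiments_per_zone):
                terms.append(term)
            else:
                log.warning("climate zone dropped: fewer than %d experiments per zone",
                            config.min_experiments_per_zone)
        elif term == "soil_depth":
            if effects_rv["soil_depth"].notna().all() and effects_rv["soil_depth"].nunique() > 1:
                terms.append(term)
        else:
            terms.append(term)
    return terms


def _re_spec(config: PipelineConfig, outcome: str, effects_rv: pd.DataFrame) -> RandomEffectsSpec:
    use_method = outcome in config.method_re_outcomes and \
        effects_rv["method_subtype"].astype(str).replace("", pd.NA).nunique() > 1
    return RandomEffectsSpec(method="method_subtype" if use_method else None)


def run_pipeline(config: PipelineConfig, observations: pd.DataFrame | None = None) -> ReportBundle:
    """Run the full synthesis and return every report table.

    ``observations`` may be a pre-read table; otherwise the configured
    synthetic corpora are generated.  Failures in a single stage carry the
    stage name and offending outcome.
    """
    if observations is None:
        observations, _ = simulate_observations(config)
    effects, audit = es.build_effect_sizes(
        observations, allow_nonsignificant=config.allow_nonsignificant
    )
    sufficiency = es.sufficiency_filter(
        effects, config.min_obs_effect, config.min_experiments_effect
    )
    explanatory = es.sufficiency_filter(
        effects, config.min_obs_explanatory, config.min_experiments_explanatory
    ).set_index("response_variable")["eligible"]

    overall_rows, averaged, flavors, predictions = [], {}, {}, {}
    grid = build_scenario_grid(
        config.scenario_amounts, config.scenario_n_concentrations,
        days=config.scenario_days, climate_code=config.scenario_climate,
    )
    for _, row in sufficiency.iterrows():
        outcome = row["response_variable"]
        if not row["eligible"]:
            log.warning("outcome %s below effect-size sufficiency threshold", outcome)
            continue
        sub = effects[effects["response_variable"] == outcome]
        re_spec = _re_spec(config, outcome, sub)
        try:
            fit = fit_meta_model(sub, (), re_spec, method="REML", weighting=config.weighting)
        except Exception as err:  # noqa: BLE001 - stage context
            raise RuntimeError(f"stage overall-fit failed for outcome {outcome}: {err}") from err
        rep = report_overall_effect(fit, level=config.ci_level)
        overall_rows.append({
            "response_variable": outcome, "n_obs": row["n_obs"],
            "n_experiments": row["n_experiments"],
            "lnrr": rep["lnrr"], "lnrr_ci_lower": rep["lnrr_ci"][0],
            "lnrr_ci_upper": rep["lnrr_ci"][1], "ratio": rep["ratio"],
            "ratio_ci_lower": rep["ratio_ci"][0], "ratio_ci_upper": rep["ratio_ci"][1],
        })
        if not explanatory.get(outcome, False):
            continue
        terms = _moderator_terms(config, sub)
        try:
            main_set = fit_model_set(sub, terms, re_spec, interactions=False,
                                     weighting=config.weighting)
            int_set = fit_model_set(sub, terms, re_spec, interactions=True,
                                    mode=config.interaction_mode, weighting=config.weighting)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"stage model-averaging failed for outcome {outcome}: {err}") from err
        chosen, flavor = select_model_set(main_set, int_set, rule=config.set_selection_rule)
        flavors[outcome] = flavor
        averaged[outcome] = main_set.average(
            level=config.ci_level, cutoff=config.importance_cutoff
        ).table
        predictions[outcome] = {
            sc: predict_scenario(chosen, sc, level=config.ci_level) for sc in grid
        }

    overall = pd.DataFrame(overall_rows)
    scenario_report, rankings = None, None
    if predictions:
        polarity = {rv: config.polarity[rv] for rv in predictions if rv in config.polarity}
        missing = [rv for rv in predictions if rv not in config.polarity]
        if missing:
            raise KeyError(f"stage scenarios: no polarity assumption for outcomes {missing}")
        scores = []
        for sc in grid:
            preds = {rv: predictions[rv][sc] for rv in predictions}
            scores.append(tabulate_benefits_harms(preds, polarity, scenario=sc))
        scenario_report = scores_to_frame(scores)
        rankings = {
            "maximize_benefits": [s.scenario.key() for s in
                                  rank_scenarios(scores, "maximize_benefits")],
            "minimize_harms": [s.scenario.key() for s in
                               rank_scenarios(scores, "minimize_harms")],
        }
    return ReportBundle(
        effects=effects, audit=audit, sufficiency=sufficiency, overall=overall,
        averaged=averaged, selected_flavor=flavors,
        scenario_report=scenario_report, rankings=rankings,
    )
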