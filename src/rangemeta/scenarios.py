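""""Equal inputs" scenario analysis: grid predictions and benefit/harm scores.

Overall effect sizes summarise the published record, in which each outcome
was studied under different amendment amounts, materials and time frames.
The scenario engine instead asks what a *consistent* application strategy
would do: predictions from the averaged model set are generated over a grid
of amendment amount × amendment N concentration (defaults 10–50 Mg/ha ×
1.2–3.6 % N, 25 scenarios), with time since application fixed at three
years and the climate dummy set to 0.5 (halfway between dryland = 0 and
Mediterranean = 1).  Predictions use the multimodel set (main effects only
or with all two-way interactions) with the lowest AIC.

Each outcome carries a polarity assumption — whether a positive effect size
is a societal benefit (e.g. soil organic C, ANPP) or a harm (e.g. runoff P,
soil Pb).  Per scenario, outcomes whose 95 % CI excludes zero count as
*certain* benefits or harms (the primary ranking criterion); the rest count
as *leaning* by the sign of the prediction (the secondary criterion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .meta_model import build_design
from .model_averaging import ModelSet

__all__ = [
    "Scenario",
    "ScenarioScore",
    "DEFAULT_AMOUNTS",
    "DEFAULT_N_CONCENTRATIONS",
    "DEFAULT_DAYS",
    "DEFAULT_CLIMATE_CODE",
    "DEFAULT_POLARITY",
    "build_scenario_grid",
    "select_model_set",
    "predict_scenario",
    "tabulate_benefits_harms",
    "rank_scenarios",
]

DEFAULT_AMOUNTS = (10.0, 20.0, 30.0, 40.0, 50.0)  # Mg/ha
DEFAULT_N_CONCENTRATIONS = (1.2, 1.8, 2.4, 3.0, 3.6)  # % total N
DEFAULT_DAYS = 3 * 365.25  # three years after application
DEFAULT_CLIMATE_CODE = 0.5  # halfway between dryland (0) and Mediterranean (1)

#: polarity of a positive effect size per outcome
DEFAULT_POLARITY: dict[str, str] = {
    "soil_organic_c": "positive_is_benefit",
    "anpp": "positive_is_benefit",
    "plant_diversity": "positive_is_benefit",
    "plant_tissue_n": "positive_is_benefit",
    "water_holding_capacity": "positive_is_benefit",
    "soil_pb": "positive_is_harm",
    "plant_tissue_pb": "positive_is_harm",
    "soil_co2": "positive_is_harm",
    "runoff_quantity": "positive_is_harm",
    "runoff_p": "positive_is_harm",
    "runoff_nitrate": "positive_is_harm",
}


@dataclass(frozen=True)
class Scenario:
    """One hypothetical application strategy (fixed covariate values)."""

    amount_applied: float  # Mg/ha
    amendment_n: float  # % total N
    days_since_application: float = DEFAULT_DAYS
    climate_code: float = DEFAULT_CLIMATE_CODE

    def key(self) -> tuple[float, float]:
        return (self.amount_applied, self.amendment_n)


def build_scenario_grid(
    amounts: Sequence[float] | None = None,
    n_concentrations: Sequence[float] | None = None,
    days: float = DEFAULT_DAYS,
    climate_code: float = DEFAULT_CLIMATE_CODE,
) -> list[Scenario]:
    """Cartesian product of application amounts and N concentrations."""
    amounts = DEFAULT_AMOUNTS if amounts is None else tuple(amounts)
    n_concentrations = (
        DEFAULT_N_CONCENTRATIONS if n_concentrations is None else tuple(n_concentrations)
    )
    if not amounts or not n_concentrations:
        raise ValueError("scenario value lists must be nonempty")
    if any(a <= 0 for a in amounts) or any(n <= 0 for n in n_concentrations):
        raise ValueError("scenario values must be positive")
    return [
        Scenario(a, n, days_since_application=days, climate_code=climate_code)
        for a in amounts
        for n in n_concentrations
    ]


def select_model_set(
    main_only_set: ModelSet,
    interaction_set: ModelSet,
    rule: str = "min_aic",
) -> tuple[ModelSet, str]:
    """Choose the multimodel set used for prediction: lowest AIC wins.

    ``rule="min_aic"`` compares the minimum member AIC of each set (the
    default reading of "set AIC"); ``rule="weighted_mean_aic"`` compares the
    Akaike-weighted mean member AIC.  Ties go to the main-effects set on
    parsimony grounds.
    """
    if rule == "min_aic":
        a_main, a_int = main_only_set.min_aic, interaction_set.min_aic
    elif rule == "weighted_mean_aic":
        a_main, a_int = main_only_set.weighted_mean_aic, interaction_set.weighted_mean_aic
    else:
        raise ValueError("rule must be 'min_aic' or 'weighted_mean_aic'")
    if a_int < a_main:
        return interaction_set, "with_two_way_interactions"
    return main_only_set, "main_only"


def _scenario_row(model_set: ModelSet, scenario: Scenario) -> pd.DataFrame:
    """One-row standardised covariate frame for design construction."""
    raw = {
        "amount_applied": scenario.amount_applied,
        "amendment_n": scenario.amendment_n,
        "days_since_application": scenario.days_since_application,
    }
    values: dict[str, float] = {"climate_zone": scenario.climate_code}
    tr = model_set.transform
    used = {t for terms in model_set.term_sets for t in _flatten(terms)}
    for term in used:
        if term == "climate_zone":
            continue
        if tr is None or term not in tr.stats:
            raise ValueError(
                f"no stored transform statistics for term {term!r}; scenario "
                "prediction must reuse fit-time standardisation"
            )
        if term in raw:
            mu, sd = tr.stats[term]
            value = raw[term]
            if value <= 0:
                raise ValueError(f"scenario value for {term!r} must be positive")
            values[term] = (math.log(value) - mu) / sd
        else:
            # covariates without scenario values (soil depth) sit at the
            # transform zero-point, i.e. the geometric mean of the data
            values[term] = 0.0
    return pd.DataFrame({k: [v] for k, v in values.items()})


def _flatten(terms):
    for t in terms:
        if isinstance(t, tuple):
            yield from t
        else:
            yield t


def predict_scenario(
    model_set: ModelSet, scenario: Scenario, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Model-averaged prediction of lnRR for one scenario with its CI.

    Each member contributes x'β_i with its Wald SE; the averaged prediction
    and unconditional SE combine them with the Akaike weights via the
    Buckland formula, so the interval reflects model-selection uncertainty.
    """
    from scipy.stats import norm

    row = _scenario_row(model_set, scenario)
    preds, ses = [], []
    for terms, fit in zip(model_set.term_sets, model_set.fits):
        X, _ = build_design(row, terms)
        p, s = fit.predict(X)
        preds.append(float(p[0]))
        ses.append(float(s[0]))
    preds = np.array(preds)
    ses = np.array(ses)
    w = model_set.weights
    pred = float(w @ preds)
    se = float(w @ np.sqrt(ses**2 + (preds - pred) ** 2))
    z = norm.ppf(1 - (1 - level) / 2)
    return pred, (pred - z * se, pred + z * se)


@dataclass
class ScenarioScore:
    """Benefit/harm tallies for one scenario across all predicted outcomes."""

    scenario: Scenario
    predictions: dict[str, tuple[float, tuple[float, float]]] = field(default_factory=dict)
    certain_benefits: int = 0
    certain_harms: int = 0
    leaning_benefits: int = 0
    leaning_harms: int = 0

    @property
    def n_outcomes(self) -> int:
        return len(self.predictions)


def tabulate_benefits_harms(
    predictions: Mapping[str, tuple[float, tuple[float, float]]],
    polarity_map: Mapping[str, str] | None = None,
    scenario: Scenario | None = None,
) -> ScenarioScore:
    """Count certain/leaning benefits and harms for one scenario.

    ``predictions`` maps outcome -> (lnrr, (ci_lower, ci_upper)).  A
    prediction whose CI excludes zero is *certain*; otherwise it *leans* by
    its sign.  The polarity map decides whether a positive effect is a
    benefit or a harm; an exactly-zero leaning prediction (measure-zero
    case) counts toward neither side.
    """
    polarity_map = DEFAULT_POLARITY if polarity_map is None else polarity_map
    score = ScenarioScore(
        scenario=scenario or Scenario(float("nan"), float("nan")),
        predictions=dict(predictions),
    )
    for outcome in sorted(predictions):
        pred, (lo, hi) = predictions[outcome]
        if outcome not in polarity_map:
            raise KeyError(f"no polarity assumption for outcome {outcome!r}")
        positive_is_benefit = polarity_map[outcome] == "positive_is_benefit"
        certain = lo > 0 or hi < 0
        beneficial = (pred > 0) == positive_is_benefit and pred != 0
        if certain:
            if beneficial:
                score.certain_benefits += 1
            else:
                score.certain_harms += 1
        elif pred != 0:
            if beneficial:
                score.leaning_benefits += 1
            else:
                score.leaning_harms += 1
        # pred == 0 with an overlapping CI leans toward neither side
    return score


def rank_scenarios(
    scores: Sequence[ScenarioScore], objective: str = "maximize_benefits"
) -> list[ScenarioScore]:
    """Order scenarios by the primary (certain) then secondary (leaning) counts.

    Fully tied scores fall back to ascending (amount, N) for a deterministic
    order.
    """
    if objective == "maximize_benefits":
        def sort_key(s: ScenarioScore):
            return (-s.certain_benefits, -s.leaning_benefits, *s.scenario.key())
    elif objective == "minimize_harms":
        def sort_key(s: ScenarioScore):
            return (s.certain_harms, s.leaning_harms, *s.scenario.key())
    else:
        raise ValueError("objective must be 'maximize_benefits' or 'minimize_harms'")
    return sorted(scores, key=sort_key)


def scores_to_frame(scores: Sequence[ScenarioScore]) -> pd.DataFrame:
    """Flat scenario report: grid values, per-outcome predictions, tallies."""
    rows = []
    for s in scores:
        row: dict = {
            "amount_applied": s.scenario.amount_applied,
            "amendment_n": s.scenario.amendment_n,
        }
        for outcome in sorted(s.predictions):
            pred, (lo, hi) = s.predictions[outcome]
            row[f"{outcome}_lnrr"] = pred
            row[f"{outcome}_ci_lower"] = lo
            row[f"{outcome}_ci_upper"] = hi
        row.update(
            certain_benefits=s.certain_benefits,
            certain_harms=s.certain_harms,
            leaning_benefits=s.leaning_benefits,
            leaning_harms=s.leaning_harms,
        )
        rows.append(row)
    return pd.DataFrame(rows)
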