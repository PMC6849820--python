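"""All-subsets model sets, Akaike weights, importance and model averaging.

For each outcome, every combination of the candidate moderators defines a
member model; members are fitted by ML (AICs from restricted likelihoods are
not comparable across fixed-effect structures) and weighted by Akaike
weights w_i ∝ exp(-ΔAIC_i/2), read as model probabilities.  A term's
importance is the summed weight of the members containing it, and
model-averaged coefficients use full (zero-substitution) averaging with the
unconditional standard error of Buckland, Burnham & Augustin:

    SE_bar = Σ_i w_i * sqrt(se_i^2 + (β_i − β_bar)^2)

which folds model-selection uncertainty into the interval.  Terms are called
important when importance ≥ 0.8, and more conservatively when additionally
the 95% unconditional CI excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meta_model import (
    MetaRegression,
    MetaRegressionResults,
    ModeratorTransform,
    RandomEffectsSpec,
)

__all__ = [
    "enumerate_models",
    "akaike_weights",
    "term_importance",
    "averaged_coefficients",
    "classify_terms",
    "ModelSet",
    "AveragedModelResults",
    "fit_model_set",
]


def _term_name(term) -> str:
    if isinstance(term, tuple):
        return f"{term[0]}:{term[1]}"
    return str(term)


def enumerate_models(
    main_terms: Sequence[str],
    interactions: bool = False,
    covariate_only: Sequence[str] = ("soil_depth",),
    mode: str = "permissive",
) -> list[tuple]:
    """Enumerate fixed-effect term sets for the all-subsets model space.

    ``interactions=False`` gives all 2^m subsets of the main terms
    (including the intercept-only model).  With interactions, every two-way
    product of eligible main terms may enter, subject to marginality (both
    parents present); covariate-only terms never interact.  ``mode``
    controls the interaction space: ``"permissive"`` enumerates every
    marginality-valid combination, ``"full_main"`` restricts to members
    carrying the complete main-effect set plus any subset of pairs.
    """
    main_terms = list(main_terms)
    models: list[tuple] = []
    if not interactions:
        for r in range(len(main_terms) + 1):
            for subset in combinations(main_terms, r):
                models.append(tuple(subset))
        return models
    eligible = [t for t in main_terms if t not in covariate_only]
    all_pairs = list(combinations(eligible, 2))
    if mode == "full_main":
        base = tuple(main_terms)
        for r in range(len(all_pairs) + 1):
            for pairs in combinations(all_pairs, r):
                models.append(base + tuple(pairs))
        return models
    if mode != "permissive":
        raise ValueError("mode must be 'permissive' or 'full_main'")
    for r in range(len(main_terms) + 1):
        for subset in combinations(main_terms, r):
            present = set(subset)
            valid_pairs = [p for p in all_pairs if p[0] in present and p[1] in present]
            for q in range(len(valid_pairs) + 1):
                for pairs in combinations(valid_pairs, q):
                    models.append(tuple(subset) + tuple(pairs))
    return models


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights from AIC values: w_i ∝ exp(-(AIC_i - min AIC)/2)."""
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0 or not np.all(np.isfinite(aics)):
        raise ValueError("AIC values must be finite and non-empty")
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def term_importance(term_sets: Sequence[tuple], weights: Sequence[float]) -> dict[str, float]:
    """Summed Akaike weight of the members containing each term."""
    weights = np.asarray(weights, dtype=float)
    all_terms: dict[str, float] = {}
    for terms, w in zip(term_sets, weights):
        for t in terms:
            all_terms[_term_name(t)] = all_terms.get(_term_name(t), 0.0) + float(w)
    return all_terms


def averaged_coefficients(
    term_sets: Sequence[tuple],
    weights: Sequence[float],
    betas: Sequence[dict],
    ses: Sequence[dict],
    level: float = 0.95,
    conditional: bool = False,
) -> pd.DataFrame:
    """Model-averaged coefficients with unconditional SEs and CIs.

    ``betas``/``ses`` map coefficient name -> value per member model.  Under
    full averaging (the default) a term absent from a member contributes
    β_i = 0, se_i = 0; conditional averaging renormalises the weights over
    the members that contain the term.
    """
    weights = np.asarray(weights, dtype=float)
    names: list[str] = []
    for b in betas:
        for name in b:
            if name not in names:
                names.append(name)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    rows = []
    for name in names:
        present = np.array([name in b for b in betas])
        beta_i = np.array([b.get(name, 0.0) for b in betas])
        se_i = np.array([s.get(name, 0.0) for s in ses])
        if conditional:
            wsum = weights[present].sum()
            if wsum == 0:
                continue
            w = np.where(present, weights, 0.0) / wsum
        else:
            w = weights
        beta_bar = float(w @ beta_i)
        se_bar = float(w @ np.sqrt(se_i**2 + (beta_i - beta_bar) ** 2))
        rows.append(
            {
                "term": name,
                "beta": beta_bar,
                "se": se_bar,
                "ci_lower": beta_bar - z * se_bar,
                "ci_upper": beta_bar + z * se_bar,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def classify_terms(
    importance: dict[str, float], cis: pd.DataFrame, cutoff: float = 0.8
) -> dict[str, str]:
    """Two-tier importance classification.

    ``important_both`` needs importance ≥ cutoff and a CI excluding zero;
    ``important_importance_only`` passes only the importance cutoff; the CI
    criterion alone never rescues a below-cutoff term.
    """
    out = {}
    for term, imp in importance.items():
        lo = float(cis.loc[term, "ci_lower"])
        hi = float(cis.loc[term, "ci_upper"])
        if imp >= cutoff:
            out[term] = "important_both" if (lo > 0 or hi < 0) else "important_importance_only"
        else:
            out[term] = "not_important"
    return out


# ---------------------------------------------------------------------------
# fitted model sets


@dataclass
class ModelSet:
    """All-subsets candidate set fitted on one outcome's effect sizes."""

    term_sets: list[tuple]
    fits: list[MetaRegressionResults]
    weights: np.ndarray
    transform: ModeratorTransform | None
    flavor: str  # "main_only" | "with_two_way_interactions"

    @property
    def min_aic(self) -> float:
        return float(min(f.aic for f in self.fits))

    @property
    def weighted_mean_aic(self) -> float:
        return float(self.weights @ np.array([f.aic for f in self.fits]))

    def average(self, level: float = 0.95, conditional: bool = False,
                cutoff: float = 0.8) -> "AveragedModelResults":
        betas = [f.params.to_dict() for f in self.fits]
        ses = [f.bse.to_dict() for f in self.fits]
        table = averaged_coefficients(
            self.term_sets, self.weights, betas, ses, level=level,
            conditional=conditional,
        )
        importance = term_importance(self.term_sets, self.weights)
        importance["intercept"] = 1.0
        table.insert(0, "importance", [importance[t] for t in table.index])
        cls = classify_terms(importance, table, cutoff=cutoff)
        table["classification"] = [cls[t] for t in table.index]
        return AveragedModelResults(table=table, model_set=self, level=level, cutoff=cutoff)


@dataclass
class AveragedModelResults:
    """Model-averaged report: the machine twin of a coefficients table.

    ``table`` has one row per term: importance, averaged beta, unconditional
    SE, CI bounds and the two-tier classification.
    """

    table: pd.DataFrame
    model_set: ModelSet
    level: float = 0.95
    cutoff: float = 0.8

    @property
    def importance(self) -> pd.Series:
        return self.table["importance"]

    def summary(self) -> str:
        lines = [
            f"Model-averaged coefficients ({self.model_set.flavor}, "
            f"{len(self.model_set.fits)} members, 95% unconditional CIs)",
        ]
        for term, row in self.table.iterrows():
            lines.append(
                f"  {term:<34s} imp={row['importance']:.3f}  b={row['beta']:+.4f} "
                f"(SE {row['se']:.4f}, CI {row['ci_lower']:+.4f} to "
                f"{row['ci_upper']:+.4f})  {row['classification']}"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def fit_model_set(
    effects: pd.DataFrame,
    main_terms: Sequence[str],
    re_spec: RandomEffectsSpec | None = None,
    interactions: bool = False,
    covariate_only: Sequence[str] = ("soil_depth",),
    mode: str = "permissive",
    weighting: str = "unweighted",
    **fit_kwargs,
) -> ModelSet:
    """Fit the all-subsets candidate set for one outcome by ML.

    All members share the moderator standardisation fitted once on the
    supplied effect sizes and one random-effects specification.
    """
    re_spec = re_spec or RandomEffectsSpec()
    continuous = sorted({t for t in main_terms if t != "climate_zone"})
    transform = ModeratorTransform().fit(effects, continuous) if continuous else None
    term_sets = enumerate_models(
        main_terms, interactions=interactions, covariate_only=covariate_only, mode=mode
    )
    fits = []
    for terms in term_sets:
        model = MetaRegression.from_effects(effects, terms, re_spec, transform)
        fits.append(model.fit(method="ML", weighting=weighting, **fit_kwargs))
    weights = akaike_weights([f.aic for f in fits])
    flavor = "with_two_way_interactions" if interactions else "main_only"
    return ModelSet(term_sets=term_sets, fits=fits, weights=weights,
                    transform=transform, flavor=flavor)
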