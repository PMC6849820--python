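"""Seeded synthetic literature corpora with known ground truth.

The generator emulates the hierarchical structure of an extracted
meta-analytic dataset — experiments containing publications containing
observations — together with the moderator distributions and the messy
reporting found in the primary literature: some rows report arm standard
deviations, some standard errors, some only an exact p-value, and some only
a binned significance statement ("0.01<p<0.05").

True effect sizes follow the same multilevel model the pipeline fits,

    lnRR_i = b0 + x_i' b + u_exp + u_pub (+ u_method) + e_i,

with moderator effects expressed on the standardised (log, centered,
scaled) scale used in fitting, so recovered coefficients are directly
comparable to the generating ones.  Arm means are constructed to reproduce
each row's true lnRR exactly, and arm SDs follow a fixed per-arm
coefficient of variation; reporting degradation only ever *removes*
information, so the ground-truth record retains every generating value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effect_sizes import OBSERVATION_COLUMNS

__all__ = ["CorpusConfig", "GroundTruth", "generate_corpus", "degrade_reporting", "spawn_seed"]

#: p-value bins conventional in the source literature (upper bound ``None``
#: marks the non-significant bin, excluded by the default pipeline)
P_RANGE_BINS = (
    (0.001, "p<0.001"),
    (0.01, "0.001<p<0.01"),
    (0.05, "0.01<p<0.05"),
    (None, "p>0.05"),
)


@dataclass(frozen=True)
class CorpusConfig:
    """Generating conditions for one synthetic outcome's corpus."""

    seed: int
    response_variable: str = "soil_organic_c"
    n_experiments: int = 30
    publications_per_experiment: tuple[int, int] = (1, 2)  # inclusive range
    observations_per_publication: tuple[int, int] = (2, 6)
    true_intercept: float = float(np.log(1.34))
    #: standardised-scale slopes; keys are moderator names or (a, b) pairs
    true_moderator_effects: Mapping = field(default_factory=dict)
    sigma_experiment: float = 0.2
    sigma_publication: float = 0.1
    sigma_method: float = 0.0
    sigma_residual: float = 0.15
    method_subtypes: tuple[str, ...] = ()
    #: moderator distributions (log-uniform ranges; climate is Bernoulli)
    amount_range: tuple[float, float] = (1.0, 100.0)  # Mg/ha
    amendment_n_range: tuple[float, float] = (0.5, 6.0)  # % N
    days_range: tuple[float, float] = (30.0, 3650.0)
    soil_depth_range: tuple[float, float] = (5.0, 30.0)  # cm
    p_mediterranean: float = 0.4
    #: reporting mix over {sd, se, p_exact, p_range}
    reporting_mix: Mapping[str, float] = field(
        default_factory=lambda: {"sd": 0.4, "se": 0.2, "p_exact": 0.1, "p_range": 0.3}
    )
    replicate_range: tuple[int, int] = (3, 6)
    control_mean_scale: float = 10.0
    arm_cv: float = 0.25

    def __post_init__(self):
        mix = dict(self.reporting_mix)
        if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
            raise ValueError("reporting_mix must be non-negative and sum to 1")
        for s in (self.sigma_experiment, self.sigma_publication,
                  self.sigma_method, self.sigma_residual):
            if s < 0:
                raise ValueError("variance-component SDs must be >= 0")
        if self.sigma_method > 0 and len(self.method_subtypes) < 2:
            raise ValueError("sigma_method > 0 requires at least two method subtypes")


@dataclass
class GroundTruth:
    """Generating record: config, coefficients, components, per-row truth."""

    config: CorpusConfig
    betas: dict
    sigmas: dict[str, float]
    true_lnrr: np.ndarray
    standardization: dict[str, tuple[float, float]]
    full_table: pd.DataFrame  # pre-degradation table (all reporting intact)


def spawn_seed(seed: int, *keys) -> int:
    """Deterministic child seed for a pipeline stage (stays below 2^31)."""
    ss = np.random.SeedSequence([int(seed)] + [abs(hash(k)) % (2**31) for k in keys])
    return int(ss.generate_state(1)[0] % (2**31))


def _log_uniform(rng, lo, hi, size):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate_corpus(config: CorpusConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one synthetic corpus and its ground-truth record.

    Returns the observation table (exact schema consumed by the
    effect-size builder, after reporting degradation per the configured
    mix) and a :class:`GroundTruth` carrying everything the generator knew.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for e in range(config.n_experiments):
        exp_id = f"exp{e:03d}"
        u_exp = rng.normal(0.0, config.sigma_experiment)
        climate = "mediterranean" if rng.random() < config.p_mediterranean else "dryland"
        n_pubs = rng.integers(config.publications_per_experiment[0],
                              config.publications_per_experiment[1] + 1)
        for p in range(n_pubs):
            pub_id = f"{exp_id}_pub{p:02d}"
            u_pub = rng.normal(0.0, config.sigma_publication)
            n_obs = rng.integers(config.observations_per_publication[0],
                                 config.observations_per_publication[1] + 1)
            for _ in range(n_obs):
                rows.append(dict(experiment_id=exp_id, publication_id=pub_id,
                                 climate_zone=climate, u_exp=u_exp, u_pub=u_pub))
    n = len(rows)
    df = pd.DataFrame(rows)
    df["response_variable"] = config.response_variable
    df["amount_applied"] = _log_uniform(rng, *config.amount_range, n)
    df["amendment_n"] = _log_uniform(rng, *config.amendment_n_range, n)
    df["days_since_application"] = _log_uniform(rng, *config.days_range, n)
    df["soil_depth"] = _log_uniform(rng, *config.soil_depth_range, n)
    if config.method_subtypes:
        df["method_subtype"] = rng.choice(list(config.method_subtypes), size=n)
        u_meth = {m: rng.normal(0.0, config.sigma_method) for m in config.method_subtypes}
        df["u_meth"] = df["method_subtype"].map(u_meth)
    else:
        df["method_subtype"] = ""
        df["u_meth"] = 0.0

    # standardised moderator columns, exactly as the fitting pipeline builds them
    standardization: dict[str, tuple[float, float]] = {}
    std_cols: dict[str, np.ndarray] = {}
    for term in ("amount_applied", "amendment_n", "days_since_application", "soil_depth"):
        logs = np.log(df[term].to_numpy())
        mu, sd = float(logs.mean()), float(logs.std(ddof=1))
        standardization[term] = (mu, sd)
        std_cols[term] = (logs - mu) / sd
    std_cols["climate_zone"] = (df["climate_zone"] == "mediterranean").to_numpy(float)

    fixed = np.full(n, config.true_intercept)
    betas = {"intercept": config.true_intercept}
    for term, beta in config.true_moderator_effects.items():
        if isinstance(term, tuple):
            col = std_cols[term[0]] * std_cols[term[1]]
            betas[f"{term[0]}:{term[1]}"] = beta
        else:
            col = std_cols[term]
            betas[str(term)] = beta
        fixed = fixed + beta * col

    eps = rng.normal(0.0, config.sigma_residual, size=n)
    true_lnrr = fixed + df["u_exp"].to_numpy() + df["u_pub"].to_numpy() \
        + df["u_meth"].to_numpy() + eps

    df["mean_ctl"] = config.control_mean_scale * np.exp(rng.normal(0.0, 0.3, size=n))
    df["mean_trt"] = df["mean_ctl"] * np.exp(true_lnrr)
    df["n_trt"] = rng.integers(config.replicate_range[0], config.replicate_range[1] + 1, size=n)
    df["n_ctl"] = rng.integers(config.replicate_range[0], config.replicate_range[1] + 1, size=n)
    df["sd_trt"] = config.arm_cv * df["mean_trt"]
    df["sd_ctl"] = config.arm_cv * df["mean_ctl"]
    df["se_trt"] = np.nan
    df["se_ctl"] = np.nan
    df["p_exact"] = np.nan
    df["p_range"] = ""

    full = df[OBSERVATION_COLUMNS].copy()
    degraded = degrade_reporting(full, config.reporting_mix, rng)
    truth = GroundTruth(
        config=config,
        betas=betas,
        sigmas={
            "experiment": config.sigma_experiment**2,
            "publication": config.sigma_publication**2,
            "method": config.sigma_method**2,
            "residual": config.sigma_residual**2,
        },
        true_lnrr=true_lnrr,
        standardization=standardization,
        full_table=full,
    )
    return degraded, truth


def _sd_path_p(row) -> float:
    """Two-sided p implied by the SD-path Wald statistic of a row."""
    lnrr = np.log(row.mean_trt / row.mean_ctl)
    v = row.sd_trt**2 / (row.n_trt * row.mean_trt**2) \
        + row.sd_ctl**2 / (row.n_ctl * row.mean_ctl**2)
    if v <= 0 or lnrr == 0:
        return 1.0 - 1e-12
    p = 2.0 * stats.norm.sf(abs(lnrr) / np.sqrt(v))
    return float(min(max(p, 1e-300), 1.0 - 1e-12))


def degrade_reporting(
    observations: pd.DataFrame,
    mix: Mapping[str, float],
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Reassign rows to reporting classes, discarding richer information.

    Rows currently carrying SDs are mapped to one of {sd, se, p_exact,
    p_range} per the mix probabilities.  SE rows convert SD to SE; p rows
    carry the two-sample Wald approximation of the comparison, either as an
    exact p-value or binned into conventional significance ranges.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    classes = list(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    out = observations.copy()
    assigned = rng.choice(classes, size=len(out), p=probs / probs.sum())
    for i, (idx, row) in enumerate(out.iterrows()):
        cls = assigned[i]
        if cls == "sd":
            continue
        if cls == "se":
            out.loc[idx, "se_trt"] = row.sd_trt / np.sqrt(row.n_trt)
            out.loc[idx, "se_ctl"] = row.sd_ctl / np.sqrt(row.n_ctl)
        else:
            p = _sd_path_p(row)
            if cls == "p_exact":
                out.loc[idx, "p_exact"] = p
            else:
                for upper, label in P_RANGE_BINS:
                    if upper is None or p < upper:
                        out.loc[idx, "p_range"] = label
                        break
        out.loc[idx, ["sd_trt", "sd_ctl"]] = np.nan
    return out
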