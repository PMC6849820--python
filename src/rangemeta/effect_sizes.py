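"""Log-response-ratio effect sizes from heterogeneously reported observations.

Each observation is one treatment-vs-control comparison extracted from a field
study: means, replicate counts, and *some* measure of dispersion — a standard
deviation pair, a standard error pair, an exact p-value, or only a textual
p-value range such as ``"p<0.05"``.  The effect size is the log response ratio

    lnRR = ln(mean_trt / mean_ctl)

and its sampling variance is recovered from the best available reporting path:

    SD  ->  v = sd_t^2/(n_t m_t^2) + sd_c^2/(n_c m_c^2)
    SE  ->  convert SE to SD (sd = se * sqrt(n)) and use the SD path
    p   ->  z from the two-sided p-value, v = (lnRR / z)^2
    p-range -> p taken as the midpoint of the reported range, then as above

Observations with no usable dispersion information are excluded, never fatal:
every exclusion is recorded in an audit table.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSize",
    "log_response_ratio",
    "variance_from_sd",
    "sd_from_se",
    "p_from_range",
    "variance_from_p",
    "build_effect_size",
    "build_effect_sizes",
    "sufficiency_filter",
    "climate_zones_sufficient",
    "OBSERVATION_COLUMNS",
]

#: Required columns of the observation table (dispersion columns are optional
#: in the sense that any one reporting path suffices).
OBSERVATION_COLUMNS = [
    "response_variable",
    "experiment_id",
    "publication_id",
    "method_subtype",
    "mean_trt",
    "mean_ctl",
    "sd_trt",
    "sd_ctl",
    "se_trt",
    "se_ctl",
    "n_trt",
    "n_ctl",
    "p_exact",
    "p_range",
    "climate_zone",
    "days_since_application",
    "amount_applied",
    "amendment_n",
    "soil_depth",
]


class ObservationError(ValueError):
    """A single observation cannot yield an effect size (batch continues)."""


@dataclass(frozen=True)
class EffectSize:
    """One log response ratio with its variance and recovery provenance."""

    lnrr: float
    variance: float
    variance_source: str  # one of {"sd", "se", "p_exact", "p_range"}

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


def log_response_ratio(mean_trt: float, mean_ctl: float) -> float:
    """Natural log of the treatment/control ratio of means.

    Both means must be strictly positive; a non-positive mean is an
    extraction error and raises :class:`ObservationError`.
    """
    if not (mean_trt > 0 and mean_ctl > 0):
        raise ObservationError(
            f"log response ratio requires positive means, got "
            f"mean_trt={mean_trt!r}, mean_ctl={mean_ctl!r}"
        )
    return math.log(mean_trt / mean_ctl)


def variance_from_sd(
    mean_trt: float,
    sd_trt: float,
    n_trt: int,
    mean_ctl: float,
    sd_ctl: float,
    n_ctl: int,
) -> float:
    """Sampling variance of lnRR from arm means, SDs and replicate counts.

    Uses the delta-method variance of a log ratio without assuming equal
    variances in the two arms::

        v = sd_trt^2 / (n_trt * mean_trt^2) + sd_ctl^2 / (n_ctl * mean_ctl^2)
    """
    if not (mean_trt > 0 and mean_ctl > 0):
        raise ObservationError("variance_from_sd requires positive means")
    if sd_trt < 0 or sd_ctl < 0:
        raise ObservationError("standard deviations must be non-negative")
    if n_trt < 1 or n_ctl < 1:
        raise ObservationError("replicate counts must be >= 1")
    return sd_trt**2 / (n_trt * mean_trt**2) + sd_ctl**2 / (n_ctl * mean_ctl**2)


def sd_from_se(se: float, n: int) -> float:
    """Standard deviation implied by a standard error of the mean: sd = se*sqrt(n)."""
    if se < 0:
        raise ObservationError("standard error must be non-negative")
    if n < 1:
        raise ObservationError("replicate count must be >= 1")
    return se * math.sqrt(n)


# "p<0.05", "p < .05", "P≤0.05"
_P_UPPER = re.compile(r"^\s*p\s*[<≤]\s*(\d*\.?\d+(?:e-?\d+)?)\s*$", re.IGNORECASE)
# "0.001<p<0.01"
_P_BOTH = re.compile(
    r"^\s*(\d*\.?\d+(?:e-?\d+)?)\s*[<≤]\s*p\s*[<≤]\s*(\d*\.?\d+(?:e-?\d+)?)\s*$",
    re.IGNORECASE,
)
# "p>0.05", "p ≥ 0.05"
_P_LOWER = re.compile(r"^\s*p\s*[>≥]\s*(\d*\.?\d+(?:e-?\d+)?)\s*$", re.IGNORECASE)


def p_from_range(range_spec: str, allow_nonsignificant: bool = False) -> float:
    """Point p-value imputed as the midpoint of a reported p-value range.

    ``"p<0.05"`` has an implied lower bound of 0 and yields 0.025;
    ``"0.001<p<0.01"`` yields 0.0055.  Ranges open above ("p>0.05", "ns")
    are rejected unless ``allow_nonsignificant`` is set, in which case the
    midpoint of (bound, 1) is used — the primary literature rarely supports
    a sharper rule for non-significant reports.
    """
    if not isinstance(range_spec, str) or not range_spec.strip():
        raise ObservationError(f"unparseable p-value range: {range_spec!r}")
    text = range_spec.strip()
    m = _P_UPPER.match(text)
    if m:
        upper = float(m.group(1))
        lower = 0.0
    else:
        m = _P_BOTH.match(text)
        if m:
            lower, upper = float(m.group(1)), float(m.group(2))
        else:
            m = _P_LOWER.match(text)
            if m or text.lower() in {"ns", "n.s.", "not significant"}:
                if not allow_nonsignificant:
                    raise ObservationError(
                        f"non-significant p-range {range_spec!r} excluded "
                        "(pass allow_nonsignificant=True to impute its midpoint)"
                    )
                lower = float(m.group(1)) if m else 0.05
                upper = 1.0
            else:
                raise ObservationError(f"unparseable p-value range: {range_spec!r}")
    if not (0 <= lower < upper <= 1):
        raise ObservationError(
            f"p-value range {range_spec!r} does not satisfy 0 <= L < U <= 1"
        )
    return (lower + upper) / 2.0


def variance_from_p(lnrr: float, p: float) -> float:
    """Variance of lnRR recovered from a two-sided p-value.

    The p-value is converted to a standard-normal z-score
    (z = Phi^{-1}(1 - p/2)) and the variance follows from inverting the
    Wald statistic: v = (lnrr/z)^2.  A zero lnRR gives the degenerate
    variance 0; callers flag such observations as non-informative.
    """
    if not (0 < p < 1):
        raise ObservationError(f"p-value must lie strictly in (0, 1), got {p!r}")
    if not math.isfinite(lnrr):
        raise ObservationError("lnrr must be finite")
    if lnrr == 0.0:
        return 0.0
    z = stats.norm.isf(p / 2.0)
    return (lnrr / z) ** 2


def _present(value) -> bool:
    """Whether an optional observation field carries a usable value."""
    if value is None:
        return False
    if isinstance(value, str):
        return bool(value.strip())
    try:
        return not (isinstance(value, float) and math.isnan(value))
    except TypeError:  # pragma: no cover - exotic types
        return True


def build_effect_size(obs, allow_nonsignificant: bool = False) -> EffectSize:
    """Construct the effect size for one observation (mapping or Series).

    The variance is recovered from the first available path in precedence
    order SD -> SE -> exact p -> p-range; the chosen path is recorded for
    audit.  Raises :class:`ObservationError` when no path is available or
    the row is degenerate (e.g. lnRR = 0 with only a p-based path).
    """
    lnrr = log_response_ratio(float(obs["mean_trt"]), float(obs["mean_ctl"]))
    n_trt, n_ctl = int(obs["n_trt"]), int(obs["n_ctl"])

    if _present(obs.get("sd_trt")) and _present(obs.get("sd_ctl")):
        v = variance_from_sd(
            float(obs["mean_trt"]), float(obs["sd_trt"]), n_trt,
            float(obs["mean_ctl"]), float(obs["sd_ctl"]), n_ctl,
        )
        return EffectSize(lnrr, v, "sd")
    if _present(obs.get("se_trt")) and _present(obs.get("se_ctl")):
        v = variance_from_sd(
            float(obs["mean_trt"]), sd_from_se(float(obs["se_trt"]), n_trt), n_trt,
            float(obs["mean_ctl"]), sd_from_se(float(obs["se_ctl"]), n_ctl), n_ctl,
        )
        return EffectSize(lnrr, v, "se")
    if _present(obs.get("p_exact")) or _present(obs.get("p_range")):
        if lnrr == 0.0:
            raise ObservationError(
                "lnRR = 0 with only a p-based variance path: degenerate "
                "(zero variance) observation excluded"
            )
        if _present(obs.get("p_exact")):
            return EffectSize(lnrr, variance_from_p(lnrr, float(obs["p_exact"])), "p_exact")
        p = p_from_range(str(obs["p_range"]), allow_nonsignificant=allow_nonsignificant)
        return EffectSize(lnrr, variance_from_p(lnrr, p), "p_range")
    raise ObservationError("no dispersion information (SD/SE/p/p-range) available")


#: moderator and identifier columns carried through to the effect-size table
_CARRY = [
    "response_variable", "experiment_id", "publication_id", "method_subtype",
    "climate_zone", "days_since_application", "amount_applied", "amendment_n",
    "soil_depth",
]


def build_effect_sizes(
    observations: pd.DataFrame, allow_nonsignificant: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised effect-size construction over an observation table.

    Returns ``(effects, audit)``: the effect-size table (one row per usable
    observation, carrying lnrr, variance, variance_source and the moderators)
    and an audit table of excluded rows with machine-readable reasons.
    """
    records, audit = [], []
    for idx, row in observations.iterrows():
        try:
            es = build_effect_size(row, allow_nonsignificant=allow_nonsignificant)
        except ObservationError as err:
            audit.append({"row": idx, "reason": str(err)})
            continue
        rec = {c: row.get(c) for c in _CARRY}
        rec.update(
            row=idx, lnrr=es.lnrr, variance=es.variance,
            variance_source=es.variance_source,
        )
        records.append(rec)
    effects = pd.DataFrame.from_records(
        records, columns=["row", *_CARRY, "lnrr", "variance", "variance_source"]
    )
    audit_df = pd.DataFrame.from_records(audit, columns=["row", "reason"])
    return effects, audit_df


def sufficiency_filter(
    effects: pd.DataFrame, min_obs: int = 10, min_experiments: int = 3
) -> pd.DataFrame:
    """Data-sufficiency screen, applied per response variable.

    The default thresholds (>=10 observations from >=3 experiments) gate
    overall effect-size estimation; explanatory models use the stricter
    (50, 5).  Returns one row per response variable with observation,
    experiment and publication counts and the eligibility flag.
    """
    rows = []
    for rv, grp in effects.groupby("response_variable", sort=True):
        n_obs = len(grp)
        n_exp = grp["experiment_id"].nunique()
        n_pub = grp["publication_id"].nunique()
        rows.append(
            {
                "response_variable": rv,
                "n_obs": n_obs,
                "n_experiments": n_exp,
                "n_publications": n_pub,
                "eligible": bool(n_obs >= min_obs and n_exp >= min_experiments),
            }
        )
    return pd.DataFrame.from_records(
        rows,
        columns=["response_variable", "n_obs", "n_experiments", "n_publications", "eligible"],
    )


def climate_zones_sufficient(
    effects: pd.DataFrame, min_experiments_per_zone: int = 3,
    zones: Iterable[str] = ("dryland", "mediterranean"),
) -> bool:
    """Whether climate zone may enter as a fixed predictor.

    Climate is included only when at least ``min_experiments_per_zone``
    distinct experiments are available from each zone.
    """
    counts = effects.groupby("climate_zone")["experiment_id"].nunique()
    return all(counts.get(z, 0) >= min_experiments_per_zone for z in zones)
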