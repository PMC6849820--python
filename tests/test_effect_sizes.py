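"""Effect-size construction: lnRR, variance-recovery paths, sufficiency."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rangemeta.effect_sizes import (
    ObservationError,
    build_effect_size,
    build_effect_sizes,
    climate_zones_sufficient,
    log_response_ratio,
    p_from_range,
    sd_from_se,
    sufficiency_filter,
    variance_from_p,
    variance_from_sd,
)

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


@pytest.mark.parametrize(
    "mt, mc, expected",
    [(10, 10, 0.0), (13.4, 10, 0.2926696), (5, 20, -1.3862944)],
)
def test_log_response_ratio_values(mt, mc, expected):
    assert log_response_ratio(mt, mc) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize("mt, mc", [(0, 10), (10, 0), (-1, 10), (10, -2)])
def test_nonpositive_means_are_rejected_not_fatal(mt, mc):
    with pytest.raises(ObservationError):
        log_response_ratio(mt, mc)


@given(a=positive, b=positive)
@settings(max_examples=100, deadline=None)
def test_lnrr_reciprocal_ratios_cancel(a, b):
    assert math.exp(log_response_ratio(a, b)) * math.exp(
        log_response_ratio(b, a)
    ) == pytest.approx(1.0, rel=1e-9)


@pytest.mark.parametrize(
    "args, expected",
    [
        ((10, 0, 4, 10, 0, 4), 0.0),
        ((10, 2, 4, 10, 2, 4), 0.02),
        ((20, 4, 5, 10, 3, 5), 0.026),
    ],
)
def test_variance_from_sd_values(args, expected):
    assert variance_from_sd(*args) == pytest.approx(expected, abs=1e-12)


@given(mt=positive, st_=positive, mc=positive, sc=positive,
       nt=st.integers(1, 20), nc=st.integers(1, 20))
@settings(max_examples=100, deadline=None)
def test_variance_from_sd_symmetric_under_arm_swap(mt, st_, mc, sc, nt, nc):
    v1 = variance_from_sd(mt, st_, nt, mc, sc, nc)
    v2 = variance_from_sd(mc, sc, nc, mt, st_, nt)
    assert v1 == pytest.approx(v2, rel=1e-12)


@pytest.mark.parametrize("se, n, expected", [(0, 5, 0), (2, 4, 4), (1.5, 9, 4.5)])
def test_sd_from_se(se, n, expected):
    assert sd_from_se(se, n) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "text, expected",
    [
        ("p<0.05", 0.025),
        ("0.001<p<0.01", 0.0055),
        ("p<0.001", 0.0005),
        ("P < 0.05", 0.025),
    ],
)
def test_p_range_midpoint_rule(text, expected):
    assert p_from_range(text) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("text", ["garbage", "", "p<1.5", "0.05<p<0.01"])
def test_p_range_parse_errors(text):
    with pytest.raises(ObservationError):
        p_from_range(text)


def test_nonsignificant_ranges_excluded_unless_allowed():
    with pytest.raises(ObservationError):
        p_from_range("p>0.05")
    assert p_from_range("p>0.05", allow_nonsignificant=True) == pytest.approx(0.525)
    assert p_from_range("ns", allow_nonsignificant=True) == pytest.approx(0.525)


@pytest.mark.parametrize(
    "lnrr, p, expected, tol",
    [
        (0.0, 0.05, 0.0, 1e-12),
        (0.98, 0.05, 0.2500, 1e-3),
        (1.0, 0.3173, 1.000, 1e-3),
    ],
)
def test_variance_from_p_values(lnrr, p, expected, tol):
    assert variance_from_p(lnrr, p) == pytest.approx(expected, abs=tol)


@given(lnrr=st.floats(0.01, 5), p1=st.floats(0.001, 0.5), p2=st.floats(0.001, 0.5))
@settings(max_examples=100, deadline=None)
def test_variance_from_p_increasing_in_p(lnrr, p1, p2):
    lo, hi = sorted((p1, p2))
    if lo < hi:
        assert variance_from_p(lnrr, lo) <= variance_from_p(lnrr, hi)


@given(mt=positive, mc=positive, cv=st.floats(0.05, 0.5),
       nt=st.integers(2, 10), nc=st.integers(2, 10))
@settings(max_examples=200, deadline=None)
def test_sd_and_p_paths_agree_on_roundtrip(mt, mc, cv, nt, nc):
    """Feeding the SD-path z back through the p path recovers the variance."""
    lnrr = log_response_ratio(mt, mc)
    v_sd = variance_from_sd(mt, cv * mt, nt, mc, cv * mc, nc)
    z = abs(lnrr) / math.sqrt(v_sd)
    if z < 1e-3:  # p -> 1: the z-score is no longer resolvable from p
        return
    p = 2 * stats.norm.sf(z)
    if not (1e-300 < p < 1):
        return
    assert variance_from_p(lnrr, p) == pytest.approx(v_sd, abs=1e-9, rel=1e-9)


def _obs(**kw):
    base = dict(
        response_variable="soil_organic_c", experiment_id="e1", publication_id="p1",
        mean_trt=13.4, mean_ctl=10.0, n_trt=4, n_ctl=4,
        sd_trt=None, sd_ctl=None, se_trt=None, se_ctl=None,
        p_exact=None, p_range=None,
    )
    base.update(kw)
    return base


class TestBuildEffectSize:
    def test_sd_path_takes_precedence_over_p(self):
        es = build_effect_size(_obs(sd_trt=2.0, sd_ctl=2.0, p_range="p<0.05"))
        assert es.variance_source == "sd"

    def test_se_path_converts_to_sd(self):
        es = build_effect_size(_obs(se_trt=1.0, se_ctl=1.0))
        assert es.variance_source == "se"
        # se*sqrt(4)=2 in both arms -> same as the sd example
        assert es.variance == pytest.approx(
            variance_from_sd(13.4, 2, 4, 10, 2, 4), rel=1e-12
        )

    def test_p_range_path_chains_midpoint_and_z(self):
        es = build_effect_size(
            _obs(mean_trt=10 * math.exp(0.98), mean_ctl=10.0, p_range="p<0.05")
        )
        assert es.variance_source == "p_range"
        # midpoint 0.025 -> z = 2.241403, v = (0.98/z)^2
        assert es.variance == pytest.approx(0.191167, abs=1e-3)

    def test_no_dispersion_information_is_excluded(self):
        with pytest.raises(ObservationError):
            build_effect_size(_obs())

    def test_zero_lnrr_with_only_p_path_is_degenerate(self):
        with pytest.raises(ObservationError):
            build_effect_size(_obs(mean_trt=10.0, mean_ctl=10.0, p_exact=0.05))


def test_batch_builder_audits_exclusions():
    rows = pd.DataFrame(
        [
            _obs(sd_trt=2.0, sd_ctl=2.0),
            _obs(),  # no dispersion info
            _obs(mean_trt=-1.0, sd_trt=2.0, sd_ctl=2.0),  # bad mean
        ]
    )
    effects, audit = build_effect_sizes(rows)
    assert len(effects) == 1 and len(audit) == 2
    assert set(audit.columns) == {"row", "reason"}


@pytest.mark.parametrize(
    "n_obs, n_exp, min_obs, min_exp, eligible",
    [(10, 3, 10, 3, True), (9, 3, 10, 3, False), (60, 4, 50, 5, False), (55, 5, 50, 5, True)],
)
def test_sufficiency_thresholds(n_obs, n_exp, min_obs, min_exp, eligible):
    effects = pd.DataFrame(
        {
            "response_variable": "anpp",
            "experiment_id": [f"e{i % n_exp}" for i in range(n_obs)],
            "publication_id": [f"p{i % n_exp}" for i in range(n_obs)],
        }
    )
    out = sufficiency_filter(effects, min_obs, min_exp)
    assert bool(out.loc[0, "eligible"]) is eligible
    assert out.loc[0, "n_obs"] == n_obs and out.loc[0, "n_experiments"] == n_exp


def test_climate_rule_requires_three_experiments_per_zone():
    def frame(n_dry, n_med):
        return pd.DataFrame(
            {
                "experiment_id": [f"d{i}" for i in range(n_dry)] + [f"m{i}" for i in range(n_med)],
                "climate_zone": ["dryland"] * n_dry + ["mediterranean"] * n_med,
            }
        )

    assert climate_zones_sufficient(frame(3, 3))
    assert not climate_zones_sufficient(frame(5, 2))
    assert not climate_zones_sufficient(frame(2, 5))
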