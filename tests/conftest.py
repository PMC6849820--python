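import numpy as np
import pandas as pd
import pytest

from rangemeta.synthetic_data import CorpusConfig, generate_corpus


def balanced_one_way(m, r, mu=0.5, sigma_b=0.3, sigma_w=0.2, seed=0):
    """Balanced one-factor layout with its closed-form REML solution."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma_b, m)
    y = (mu + u[:, None] + rng.normal(0.0, sigma_w, (m, r))).ravel()
    codes = np.repeat(np.arange(m), r)
    ybar = y.reshape(m, r).mean(axis=1)
    msb = r * np.sum((ybar - y.mean()) ** 2) / (m - 1)
    msw = np.sum((y.reshape(m, r) - ybar[:, None]) ** 2) / (m * (r - 1))
    if (msb - msw) / r >= 0:
        oracle = {"between": (msb - msw) / r, "within": msw}
    else:
        oracle = {"between": 0.0, "within": np.sum((y - y.mean()) ** 2) / (len(y) - 1)}
    return y, codes, oracle, y.mean()


@pytest.fixture(scope="session")
def small_corpus():
    """One modest synthetic corpus with a known positive amount effect."""
    cfg = CorpusConfig(seed=7, true_moderator_effects={"amount_applied": 0.5})
    obs, truth = generate_corpus(cfg)
    return obs, truth


@pytest.fixture(scope="session")
def small_effects(small_corpus):
    from rangemeta.effect_sizes import build_effect_sizes

    obs, truth = small_corpus
    effects, audit = build_effect_sizes(obs)
    return effects, audit, truth
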