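import math

import numpy as np
import pandas as pd
import pytest

from txcensus.simulate import SimulationConfig, gene_annotation, sample_metadata


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=7, n_genes=400, n_planted_activations=10)


@pytest.fixture(scope="session")
def small_ann(small_cfg):
    return gene_annotation(small_cfg)


@pytest.fixture(scope="session")
def small_meta(small_cfg):
    return sample_metadata(small_cfg)


def hypergeom_pvalue(a, b, c, d, alternative="two-sided"):
    """Exhaustive Fisher p by enumerating the hypergeometric support with
    exact rational arithmetic (math.comb); independent of scipy."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    denom = math.comb(n, col1)
    probs = {x: math.comb(row1, x) * math.comb(n - row1, col1 - x) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    if alternative == "greater":
        total = sum(p for x, p in probs.items() if x >= a)
    elif alternative == "less":
        total = sum(p for x, p in probs.items() if x <= a)
    else:
        # two-sided: sum of all tables no more probable than the observed
        total = sum(p for p in probs.values() if p <= p_obs)
    return total / denom


def nb_tail_by_summation(k, mu, theta):
    """P(X >= k) for NB(mean mu, size theta) by explicit log-gamma pmf
    summation — the brute-force oracle, independent of scipy.stats.nbinom."""
    from scipy.special import gammaln
    if k <= 0:
        return 1.0
    x = np.arange(k)
    log_pmf = (gammaln(x + theta) - gammaln(theta) - gammaln(x + 1)
               + theta * np.log(theta / (theta + mu))
               + x * np.log(mu / (theta + mu)))
    return float(1.0 - np.exp(log_pmf).sum())
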