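import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_segment():
    """One whole-chromosome segment table factory for zygosity tests."""
    def make(tcn, lcn, sample="T1", chrom="chr1"):
        return pd.DataFrame([{"sample": sample, "chrom": chrom, "start": 1,
                              "end": 10 ** 9, "tcn": tcn, "lcn": lcn}])
    return make


@pytest.fixture(scope="session")
def small_cohort():
    """A 500-patient simulated cohort shared across read-only tests."""
    from bctwohit.simulate import SimulationConfig, simulate_cohort
    return simulate_cohort(SimulationConfig(seed=2024, n_patients=500))


# ---------------------------------------------------------------------------
# independent oracles (brute force / enumeration), kept free of package code


def binom_interval_oracle(p, depth, level=0.95):
    """Equal-tail binomial quantiles by exhaustive CDF scan over 0..depth."""
    from math import comb

    alpha = (1.0 - level) / 2.0
    pmf = [comb(depth, k) * p ** k * (1 - p) ** (depth - k) for k in range(depth + 1)]
    cdf, acc = [], 0.0
    for v in pmf:
        acc += v
        cdf.append(acc)
    lo = next(k for k in range(depth + 1) if cdf[k] >= alpha - 1e-12)
    hi = next(k for k in range(depth + 1) if cdf[k] >= 1 - alpha - 1e-12)
    if p == 0:
        lo = hi = 0
    if p == 1:
        lo = hi = depth
    return lo / depth, hi / depth


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric point masses."""
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c

    def pmf(k):
        return comb(c1, k) * comb(n - c1, r1 - k) / comb(n, r1)

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))


def auc_oracle(scores, labels):
    """AUC by exhaustive enumeration of all positive/negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else (0.5 if p == q else 0.0)
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up by the textbook recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
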