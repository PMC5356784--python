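import numpy as np
import pandas as pd
import pytest

from ddcnv import WellCounts, estimate_concentration
from ddcnv.simulate import SimSampleConfig, simulate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def wells_two_samples(rng):
    """Two simulated samples (one duplicated, one not) at high concentration."""
    rows = []
    for sample_id, f in (("S_dup", 1.0), ("S_norm", 0.0)):
        cfg = SimSampleConfig(
            sample_id=sample_id, true_fraction=f, reference_conc=60.0,
            n_wells=2, droplets_per_well=15000,
        )
        rows.extend(simulate_sample(cfg, rng))
    return pd.DataFrame(
        {
            "sample_id": [w.sample_id for w in rows],
            "well_id": [w.well_id for w in rows],
            "channel": [w.channel for w in rows],
            "n_total": [w.n_total for w in rows],
            "n_positive": [w.n_positive for w in rows],
        }
    )


def grid_mle_lambda(n_total, n_positive, lo=1e-6, hi=15.0, rounds=4, points=201):
    """Brute-force oracle: maximize the binomial likelihood of the partition
    model over successively refined lambda grids, then polish by solving the
    score equation d/dlam log Binom(k; n, 1 - e^-lam) = 0 on the bracketing
    interval.  (Pure grid comparison bottoms out near 1e-6: the likelihood is
    too flat around its maximum to resolve finer differences in double
    precision, so the stationarity condition provides the last digits.)"""
    from scipy.optimize import brentq
    from scipy.stats import binom

    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        ll = binom.logpmf(n_positive, n_total, -np.expm1(-grid))
        best = int(np.argmax(ll))
        step = grid[1] - grid[0]
        lo = max(grid[best] - 2 * step, 1e-12)
        hi = grid[best] + 2 * step
    score = lambda lam: n_positive / np.expm1(lam) - (n_total - n_positive)
    if score(lo) <= 0 or score(hi) >= 0:  # maximum sits on the bracket edge
        return float(grid[best])
    return float(brentq(score, lo, hi, xtol=1e-13))


def concentration_estimate(conc_copies_per_ul, n_total=15000, sample="S", channel="FAM"):
    """Build a ConcentrationEstimate whose counts are consistent with conc."""
    lam = conc_copies_per_ul * 1e-3  # 1 nL droplets
    n_positive = int(round(n_total * -np.expm1(-lam)))
    return estimate_concentration(WellCounts("w1", sample, channel, n_total, n_positive))
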