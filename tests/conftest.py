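import numpy as np
import pytest

from lipidgi.simulate import (
    CohortSimConfig,
    ScreenSimConfig,
    simulate_cohort,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Four-gene cohort with planted additive LDLc effects (common carriers
    so the pairwise battery has power at modest n)."""
    cfg = CohortSimConfig(
        n_samples=2000,
        genes=("APOB", "LDLR", "LPL", "PCSK9"),
        carrier_freq=0.05,
        n_background_snps=30,
        effects={"LDLc|PTV:APOB": -1.0, "LDLc|PTV:PCSK9": -0.8},
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_screen():
    """Six-gene screen with one planted aggravating interaction."""
    cfg = ScreenSimConfig(
        genes=("GA", "GB", "GC", "GD", "GE", "GF"),
        spots_per_array=120,
        replicates_per_treatment=8,
        effects={"GA": 1.0, "GB": 0.8, "GA__GB": 2.0, "GC": -2.4, "GD": 0.5},
        seed=7,
    )
    return simulate_screen(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ols_regime_fixture(rng, n=30, n_slopes=2):
    """Design + response whose robust fit must equal OLS exactly.

    Residuals are drawn platykurtic, orthogonalized against the design
    (so the OLS solution reproduces them exactly) and redrawn until every
    residual sits strictly inside the Huber linear region at the MAD
    scale — then all IRLS weights are one and OLS is the robust optimum.
    """
    from scipy import stats

    while True:
        X = np.column_stack([np.ones(n), rng.normal(size=(n, n_slopes))])
        e = rng.uniform(-1, 1, n)
        r = e - X @ np.linalg.lstsq(X, e, rcond=None)[0]
        mad = stats.median_abs_deviation(r, scale="normal")
        mad0 = 1.4826 * np.median(np.abs(r))  # center-zero convention
        if np.abs(r).max() < 1.25 * min(mad, mad0):
            beta = rng.normal(size=n_slopes + 1)
            return X, X @ beta + r
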