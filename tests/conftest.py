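import numpy as np
import pytest

from odapb.data import SiteData


@pytest.fixture
def two_group_site() -> SiteData:
    """10 exposed subjects with 4 events, 20 unexposed with 2 events.

    Saturated two-group design: the MLE equals the group proportions, so
    beta_hat = log(0.4/0.1) = log 4 and the robust variance of beta_hat has
    the closed form (1-p1)/(n1 p1) + (1-p0)/(n0 p0) = 0.6.
    """
    y = np.r_[np.ones(4), np.zeros(6), np.ones(2), np.zeros(18)].astype(int)
    exposed = np.r_[np.ones(10), np.zeros(20)]
    return SiteData(
        outcomes=y,
        design=np.column_stack([np.ones(30), exposed]),
        site_id="twogroup",
    )


def random_site(rng: np.random.Generator, n: int = 20, p: int = 3, site_id="rnd"):
    """Small random instance: intercept + (p-1) mixed binary/continuous
    covariates, outcome drawn from a moderate log-link risk."""
    cols = [np.ones(n)]
    for j in range(1, p):
        if j % 2 == 1:
            cols.append(rng.binomial(1, 0.4, n).astype(float))
        else:
            cols.append(rng.normal(0, 1, n))
    X = np.column_stack(cols)
    theta = np.r_[-1.0, rng.normal(0, 0.3, p - 1)]
    risk = np.minimum(np.exp(X @ theta), 1.0)
    y = rng.binomial(1, risk)
    if y.sum() == 0:  # ensure at least one event so the MLE exists
        y[rng.integers(n)] = 1
    return SiteData(outcomes=y, design=X, site_id=site_id)


@pytest.fixture
def site_factory():
    return random_site


@pytest.fixture
def three_sites(site_factory):
    rng = np.random.default_rng(42)
    return [
        site_factory(rng, n=120, p=4, site_id=f"s{i}") for i in range(3)
    ]
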