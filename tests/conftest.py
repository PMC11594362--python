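"""Shared fixtures: small simulated communities and fitted posteriors.

MCMC fixtures are session-scoped and deliberately small; they are reused
by every test that only needs *a* valid posterior rather than a
well-converged one.
"""

import numpy as np
import pytest

from odorare.detection import from_synthetic
from odorare.occupancy import McmcSettings, fit
from odorare.simulate import CommunityConfig, simulate_community


@pytest.fixture(scope="session")
def small_community():
    cfg = CommunityConfig(
        N=8, J=80, K=3, P=2, q_true=0,
        mu_beta=np.array([0.0, 0.8, -0.8]),
        tau_beta=np.full(3, 0.3),
        seed=42,
    )
    return cfg, simulate_community(cfg)


@pytest.fixture(scope="session")
def small_fit(small_community):
    cfg, ds = small_community
    arr = from_synthetic(ds)
    st = McmcSettings(
        n_chains=2, n_samples=1200, n_burn=600, n_thin=2, q=0, seed=7, max_doublings=0
    )
    return cfg, ds, arr, fit(arr, ds.X, settings=st)


@pytest.fixture(scope="session")
def small_lf_fit():
    # lambda_scale 1.5 keeps the factor well identified at this small size
    cfg = CommunityConfig(N=10, J=150, K=4, P=2, q_true=1, lambda_scale=1.5,
                          mu_beta=np.array([0.0, 0.6, -0.6]),
                          tau_beta=np.full(3, 0.4),
                          seed=11)
    ds = simulate_community(cfg)
    arr = from_synthetic(ds)
    st = McmcSettings(
        n_chains=2, n_samples=1500, n_burn=750, n_thin=2, q=1, seed=13, max_doublings=0
    )
    return cfg, ds, arr, fit(arr, ds.X, settings=st)
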