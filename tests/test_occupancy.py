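"""Occupancy-model sampler contracts: conditioning, determinism, prediction."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import ks_2samp

from odorare.detection import DetectionArray, from_synthetic
from odorare.occupancy import (
    McmcSettings,
    PriorSpec,
    fit,
    meaningful_factors,
    predict_occupancy,
    predict_richness,
)
from odorare.simulate import CommunityConfig, simulate_community


def test_z_pinned_where_detected(small_fit):
    _, ds, arr, post = small_fit
    det_any = arr.y.sum(axis=2) > 0
    assert (post.z[:, det_any] == 1).all()


def test_all_detected_everywhere_forces_z_one():
    y = np.ones((2, 10, 2), dtype=np.int8)
    arr = DetectionArray(y=y, visits=np.full((10, 2), 2), species_names=["a", "b"])
    X = np.random.default_rng(0).standard_normal((10, 1))
    st = McmcSettings(n_chains=2, n_samples=60, n_burn=20, n_thin=1, seed=0,
                      max_doublings=0)
    post = fit(arr, (X - X.mean()) / X.std(), settings=st)
    assert (post.z == 1).all()


def test_fit_shapes_and_draw_count(small_fit):
    cfg, ds, arr, post = small_fit
    S = 2 * (1200 - 600) // 2
    assert post.beta.shape == (S, cfg.N, cfg.P + 1)
    assert post.alpha.shape == (S, cfg.N, 2)
    assert post.psi.shape == (S, cfg.N, cfg.J)
    assert ((post.psi > 0) & (post.psi < 1)).all()


def test_mso_and_lfmso_interfaces_match(small_fit, small_lf_fit):
    _, _, _, mso = small_fit
    _, _, _, lf = small_lf_fit
    assert mso.lam.shape[2] == 0 and lf.lam.shape[2] == 1
    assert lf.w.shape[2] == 1
    # anchored loading is exactly one in every draw
    assert (lf.lam[:, 0, 0] == 1.0).all()


def test_seed_determinism():
    cfg = CommunityConfig(N=5, J=40, K=2, P=1, q_true=0,
                          mu_beta=np.zeros(2), tau_beta=np.full(2, 0.4), seed=2)
    ds = simulate_community(cfg)
    arr = from_synthetic(ds)
    st = McmcSettings(n_chains=2, n_samples=100, n_burn=50, n_thin=1, seed=3,
                      max_doublings=0)
    a = fit(arr, ds.X, settings=st)
    b = fit(arr, ds.X, settings=st)
    np.testing.assert_array_equal(a.beta, b.beta)
    np.testing.assert_array_equal(a.z, b.z)


def test_zero_detection_species_rejected():
    y = np.zeros((1, 5, 2), dtype=np.int8)
    arr = DetectionArray(y=y, visits=np.ones((5, 2), int), species_names=["s"])
    with pytest.raises(ValueError, match="filter_species"):
        fit(arr, np.zeros((5, 0)), settings=McmcSettings(n_chains=2, n_samples=20,
                                                         n_burn=10, max_doublings=0))


def test_q_at_least_species_count_rejected():
    y = np.ones((2, 5, 1), dtype=np.int8)
    arr = DetectionArray(y=y, visits=np.ones((5, 1), int), species_names=["a", "b"])
    with pytest.raises(ValueError, match="q must be smaller"):
        fit(arr, np.zeros((5, 0)),
            settings=McmcSettings(n_chains=2, n_samples=20, n_burn=10, q=2,
                                  max_doublings=0))


def test_slope_recovery_single_strong_covariate():
    # one species, strong effect: posterior CI should cover the truth
    cfg = CommunityConfig(N=1, J=150, K=4, P=1, q_true=0,
                          mu_beta=np.array([0.0, 2.0]),
                          tau_beta=np.array([1e-10, 1e-10]),
                          mu_alpha=np.array([0.5, 0.2]),
                          tau_alpha=np.array([1e-10, 1e-10]),
                          seed=8)
    ds = simulate_community(cfg)
    arr = from_synthetic(ds)
    st = McmcSettings(n_chains=2, n_samples=1500, n_burn=700, n_thin=2, seed=9,
                      max_doublings=0)
    post = fit(arr, ds.X, settings=st)
    lo, hi = np.quantile(post.beta[:, 0, 1], [0.025, 0.975])
    assert lo < 2.0 < hi


class TestPrediction:
    def test_origin_closed_form_q0(self, small_fit):
        _, _, _, post = small_fit
        mean, draws = predict_occupancy(post, np.zeros((1, 2)))
        expected = expit(post.beta[:, :, 0]).mean(axis=0)
        np.testing.assert_allclose(mean[:, 0], expected, rtol=1e-10)

    def test_training_site_consistency_q0(self, small_fit):
        _, ds, _, post = small_fit
        mean, _ = predict_occupancy(post, ds.X[:5])
        np.testing.assert_allclose(mean, post.psi.mean(axis=0)[:, :5], atol=1e-5)

    def test_saturation_with_extreme_covariate(self, small_fit):
        cfg, ds, _, post = small_fit
        # community slope on covariate 0 is strongly positive by design
        mean, _ = predict_occupancy(post, np.array([[8.0, 0.0]]))
        assert mean.mean() > 0.9

    def test_covariate_mismatch_rejected(self, small_fit):
        _, _, _, post = small_fit
        with pytest.raises(ValueError, match="column count"):
            predict_occupancy(post, np.zeros((1, 5)))


class TestRichness:
    def test_all_present_reaches_species_count(self, small_fit):
        cfg, _, _, post = small_fit
        rich = predict_richness(post)
        assert (rich <= cfg.N).all() and (rich >= 0).all()

    def test_bounded_below_by_observed(self, small_fit):
        _, _, arr, post = small_fit
        observed = (arr.y.sum(axis=2) > 0).sum(axis=0)
        assert (predict_richness(post) >= observed - 1e-9).all()

    def test_single_species_equals_occupancy_mean(self, small_fit):
        _, _, _, post = small_fit
        from odorare.occupancy import Posterior
        import dataclasses

        sub = dataclasses.replace(post, z=post.z[:, :1], beta=post.beta[:, :1],
                                  alpha=post.alpha[:, :1], psi=post.psi[:, :1],
                                  lam=post.lam[:, :1])
        np.testing.assert_allclose(predict_richness(sub), post.z[:, 0].mean(axis=0))


def test_metropolis_and_pg_posteriors_agree():
    cfg = CommunityConfig(N=4, J=60, K=3, P=1, q_true=0,
                          mu_beta=np.array([0.0, 1.0]), tau_beta=np.full(2, 0.3),
                          seed=21)
    ds = simulate_community(cfg)
    arr = from_synthetic(ds)
    common = dict(n_chains=2, n_samples=6000, n_burn=2500, n_thin=5,
                  max_doublings=0)
    pg = fit(arr, ds.X, settings=McmcSettings(seed=1, algorithm="pg", **common))
    mh = fit(arr, ds.X, settings=McmcSettings(seed=2, algorithm="metropolis", **common))
    # community-level marginals should be statistically indistinguishable;
    # draws are thinned further before the KS test to tame autocorrelation
    for attr, col in [("mu_beta", 1), ("mu_alpha", 0)]:
        a = getattr(pg, attr)[:, col]
        b = getattr(mh, attr)[:, col]
        assert ks_2samp(a[::7], b[::7]).pvalue > 0.005


def test_species_permutation_equivariance():
    # high detection keeps z well determined, so Monte-Carlo error on the
    # per-species occupancy means is small enough for a tight comparison
    cfg = CommunityConfig(N=5, J=80, K=3, P=1, q_true=0,
                          mu_beta=np.zeros(2), tau_beta=np.full(2, 0.4),
                          mu_alpha=np.array([0.5, 0.2]),
                          tau_alpha=np.array([0.2, 0.02]), seed=30)
    ds = simulate_community(cfg)
    arr = from_synthetic(ds)
    perm = np.array([2, 0, 4, 1, 3])
    arr_p = DetectionArray(y=arr.y[perm], visits=arr.visits,
                           species_names=[arr.species_names[i] for i in perm])
    st = McmcSettings(n_chains=2, n_samples=2000, n_burn=1000, n_thin=2, seed=5,
                      max_doublings=0)
    a = fit(arr, ds.X, settings=st)
    b = fit(arr_p, ds.X, settings=st)
    # posterior occupancy means respect the species relabeling
    np.testing.assert_allclose(
        a.psi.mean(axis=0)[perm].mean(axis=1),
        b.psi.mean(axis=0).mean(axis=1),
        atol=0.03,
    )


def test_meaningful_factor_reported_on_latent_data(small_lf_fit):
    _, _, _, post = small_lf_fit
    assert meaningful_factors(post) == [0]


def test_doubling_reported_when_not_converged():
    cfg = CommunityConfig(N=4, J=40, K=2, P=1, q_true=0,
                          mu_beta=np.zeros(2), tau_beta=np.full(2, 0.4), seed=12)
    ds = simulate_community(cfg)
    arr = from_synthetic(ds)
    # tiny chains cannot reach ESS > 100: the doubling path must engage
    st = McmcSettings(n_chains=2, n_samples=40, n_burn=20, n_thin=1, seed=3,
                      max_doublings=1)
    post = fit(arr, ds.X, settings=st)
    assert post.doublings_used == 1
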