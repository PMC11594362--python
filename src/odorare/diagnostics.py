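"""MCMC diagnostics and model criticism for the occupancy models.

Split-chain potential scale reduction (Rhat) is implemented directly from
the variance-decomposition formula; effective sample size delegates to
arviz.  WAIC and the posterior-predictive Bayesian p-value operate on the
stored posterior draws and the detection data, with the detection
likelihood conditioned on the latent presence state, so a draw with z = 0
assigns probability one to the (necessarily zero) observations at that
site.
"""

from __future__ import annotations

import warnings

import arviz as az
import numpy as np
from scipy.special import expit

__all__ = ["compute_rhat", "compute_ess", "compute_waic", "bayes_p_value"]

_LIK_FLOOR = 1e-300


def _check_chains(chain_draws: np.ndarray) -> np.ndarray:
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need draws shaped (n_chains >= 2, n_draws)")
    if x.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain")
    return x


def compute_rhat(chain_draws: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    Chains are split in half; Rhat = sqrt(((S-1)/S * W + B/S) / W) with W
    the mean within-chain variance and B the between-chain variance of the
    split-chain means.  Identical constant chains return 1.0 (the 0/0
    degenerate case of a perfectly mixed, zero-variance quantity); sampling
    noise can push the raw ratio slightly below one, so the estimate is
    floored at 1.0.
    """
    x = _check_chains(chain_draws)
    s = x.shape[1] // 2
    halves = np.concatenate([x[:, :s], x[:, s : 2 * s]], axis=0)  # (2C, s)
    w = halves.var(axis=1, ddof=1).mean()
    b = s * halves.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else np.inf
    var_plus = (s - 1) / s * w + b / s
    return float(max(1.0, np.sqrt(var_plus / w)))


def compute_ess(chain_draws: np.ndarray) -> float:
    """Autocorrelation-based effective sample size (bulk ESS via arviz).

    A zero-variance (constant) input is flagged and returns the total draw
    count: a degenerate quantity carries no autocorrelation information.
    """
    x = _check_chains(chain_draws)
    if x.var() == 0.0:
        warnings.warn("constant chains: ESS reported as total draws", stacklevel=2)
        return float(x.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(az.convert_to_dataset(x))["x"].values)


def _pointwise_likelihood_chunks(posterior, arr, chunk: int = 250):
    """Yield per-draw detection likelihoods on observed cells.

    Yields (lik, zp, y, obs_j) with lik shaped (chunk, N, n_obs_cells).
    Detection probabilities vary only over (species, visit count), so the
    logistic transform runs on visit groups and is gathered to cells.
    """
    obs_j, obs_k = np.nonzero(arr.visits > 0)
    v = arr.visits[obs_j, obs_k].astype(float)  # (n_obs,)
    vu, g_idx = np.unique(v, return_inverse=True)
    y = arr.y[:, obs_j, obs_k]  # (N, n_obs)
    S = posterior.alpha.shape[0]
    for start in range(0, S, chunk):
        a = posterior.alpha[start : start + chunk]  # (c, N, 2)
        z = posterior.z[start : start + chunk][:, :, obs_j]  # (c, N, n_obs)
        p_g = expit(a[:, :, 0, None] + a[:, :, 1, None] * vu[None, None, :])
        zp = z * p_g[:, :, g_idx]
        lik = np.where(y[None] == 1, zp, 1.0 - zp)
        yield lik, zp, y, obs_j


def compute_waic(posterior, arr) -> float:
    """Widely applicable information criterion on the deviance scale.

    WAIC = -2 (lppd - p_waic) over (species, site) units with the latent
    presence state marginalized out per draw:

        L_ij = psi_ij prod_k Bern(y_ijk | p_ijk) + (1 - psi_ij) [no detection]

    so the occupancy layer (covariates and latent factors) enters the
    criterion directly — conditioning on the sampled z would reduce model
    comparison to the detection layer alone.  lppd sums log posterior-mean
    likelihoods; p_waic sums posterior variances of the log likelihood.
    """
    obs_j, obs_k = np.nonzero(arr.visits > 0)
    v = arr.visits[obs_j, obs_k].astype(float)
    vu, g_idx = np.unique(v, return_inverse=True)
    y = arr.y[:, obs_j, obs_k].astype(float)  # (N, n_obs)
    onehot = np.zeros((obs_j.size, arr.n_sites))
    onehot[np.arange(obs_j.size), obs_j] = 1.0
    surveyed = onehot.sum(axis=0) > 0  # sites with >= 1 surveyed replicate
    no_det = (arr.y.sum(axis=2) == 0).astype(float)  # (N, J)

    S = posterior.alpha.shape[0]
    sum_lik = sum_ll = sum_ll2 = None
    chunk = 250
    for start in range(0, S, chunk):
        a = posterior.alpha[start : start + chunk]  # (c, N, 2)
        psi = posterior.psi[start : start + chunk].astype(float)  # (c, N, J)
        lp = a[:, :, 0, None] + a[:, :, 1, None] * vu[None, None, :]
        log_p = -np.logaddexp(0.0, -lp)  # log expit(lp), (c, N, V)
        log_1mp = -np.logaddexp(0.0, lp)
        ll_cells = (y[None] * log_p[:, :, g_idx]
                    + (1.0 - y[None]) * log_1mp[:, :, g_idx])
        ll_det = ll_cells @ onehot  # (c, N, J): log prod_k Bern(y | p)
        lik = psi * np.exp(ll_det) + (1.0 - psi) * no_det[None]
        ll = np.log(np.maximum(lik, _LIK_FLOOR))
        if sum_lik is None:
            sum_lik = lik.sum(axis=0)
            sum_ll = ll.sum(axis=0)
            sum_ll2 = (ll**2).sum(axis=0)
        else:
            sum_lik += lik.sum(axis=0)
            sum_ll += ll.sum(axis=0)
            sum_ll2 += (ll**2).sum(axis=0)
    lppd = np.log(np.maximum(sum_lik / S, _LIK_FLOOR))[:, surveyed].sum()
    if S > 1:
        var_ll = (sum_ll2 - sum_ll**2 / S) / (S - 1)
    else:
        var_ll = np.zeros_like(sum_ll)
    p_waic = var_ll[:, surveyed].sum()
    return float(-2.0 * (lppd - p_waic))


def bayes_p_value(posterior, arr, seed: int = 0) -> float:
    """Posterior predictive check with a site-grouped chi-square discrepancy.

    For each posterior draw, the observed and a replicated detection table
    are reduced to per-site detection totals; the discrepancy is
    sum_j (O_j - E_j)^2 / (E_j + 1/2) with E_j the expected total under the
    draw (the 1/2 guards empty expectations).  Returns the fraction of
    draws whose replicated discrepancy is at least the observed one —
    values near 0 or 1 flag misfit.
    """
    rng = np.random.default_rng(seed)
    n_ge = 0
    S = posterior.alpha.shape[0]
    onehot = None
    for lik, zp, y, obs_j in _pointwise_likelihood_chunks(posterior, arr):
        if onehot is None:
            onehot = np.zeros((obs_j.size, arr.n_sites))
            onehot[np.arange(obs_j.size), obs_j] = 1.0
            o_site = y.sum(axis=0) @ onehot
        e_site = zp.sum(axis=1) @ onehot  # (chunk, J)
        y_rep = rng.random(zp.shape) < zp
        o_rep = y_rep.sum(axis=1) @ onehot
        d_obs = ((o_site[None] - e_site) ** 2 / (e_site + 0.5)).sum(axis=1)
        d_rep = ((o_rep - e_site) ** 2 / (e_site + 0.5)).sum(axis=1)
        n_ge += int((d_rep >= d_obs).sum())
    return n_ge / S
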