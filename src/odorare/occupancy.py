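"""Multispecies occupancy models (MSO / LFMSO) fitted by Gibbs sampling.

The hierarchy: latent presence z_ij ~ Bernoulli(psi_ij) with
logit(psi_ij) = x_j' beta_i (+ lambda_i' w_j when q >= 1 latent factors are
included); replicate detections y_ijk ~ Bernoulli(z_ij * p_ijk) with
logit(p_ijk) = alpha_i0 + alpha_i1 * visits_jk; species coefficients are
community random effects beta_i ~ N(mu_beta, diag(tau_beta)) and
alpha_i ~ N(mu_alpha, diag(tau_alpha)) with normal / inverse-Gamma
hyperpriors.  Latent factors carry standard-normal priors and the loading
matrix is constrained lower-triangular with unit diagonal in its top q x q
block, which pins the factor signs and scales.

Bernoulli-logit full conditionals are made Gaussian by Polya-Gamma
augmentation; detection augmentation variables are drawn as grouped
PG(count, eta) sums over cells sharing a (species, visit-count) linear
predictor.  A random-walk Metropolis variant of the coefficient updates is
available for cross-validation of the augmented sampler.

Non-convergent runs (any monitored Rhat >= 1.1 or ESS <= 100) are retried
with samples, burn-in and thinning all doubled, up to ``max_doublings``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .detection import DetectionArray
from .diagnostics import bayes_p_value, compute_ess, compute_rhat, compute_waic
from .pg import sample_pg, sample_pg_sum

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "Posterior",
    "fit",
    "predict_occupancy",
    "predict_richness",
    "meaningful_factors",
]


@dataclass
class PriorSpec:
    """Hyperpriors: N(mu_mean, mu_var) on community means, IG(shape, scale)
    on community variances, N(0, loading_prior_var) on free loadings."""

    mu_mean: float = 0.0
    mu_var: float = 2.72
    ig_shape: float = 0.1
    ig_scale: float = 0.1
    loading_prior_var: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mu_var, self.ig_shape, self.ig_scale, self.loading_prior_var) <= 0:
            raise ValueError("variance and inverse-Gamma hyperparameters must be > 0")


@dataclass
class McmcSettings:
    n_chains: int = 3
    n_samples: int = 4000
    n_burn: int = 2000
    n_thin: int = 2
    q: int = 0
    seed: int = 0
    max_doublings: int = 2
    algorithm: str = "pg"  # "pg" (augmented Gibbs) or "metropolis" (q=0 only)

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_samples:
            raise ValueError("n_burn must be smaller than n_samples")
        if self.n_thin < 1 or self.q < 0 or self.n_chains < 1:
            raise ValueError("invalid MCMC settings")
        if self.algorithm not in ("pg", "metropolis"):
            raise ValueError("algorithm must be 'pg' or 'metropolis'")
        if self.algorithm == "metropolis" and self.q > 0:
            raise ValueError("the Metropolis variant supports q=0 only")

    def doubled(self) -> "McmcSettings":
        return McmcSettings(
            n_chains=self.n_chains,
            n_samples=2 * self.n_samples,
            n_burn=2 * self.n_burn,
            n_thin=2 * self.n_thin,
            q=self.q,
            seed=self.seed,
            max_doublings=self.max_doublings,
            algorithm=self.algorithm,
        )


@dataclass
class Posterior:
    """Flattened posterior draws (chains concatenated) plus diagnostics."""

    beta: np.ndarray  # (S, N, P+1)
    alpha: np.ndarray  # (S, N, 2)
    mu_beta: np.ndarray  # (S, P+1)
    tau_beta: np.ndarray
    mu_alpha: np.ndarray  # (S, 2)
    tau_alpha: np.ndarray
    lam: np.ndarray  # (S, N, q)
    w: np.ndarray  # (S, J, q)
    z: np.ndarray  # (S, N, J) int8
    psi: np.ndarray  # (S, N, J) float32
    n_chains: int
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    waic: float | None = None
    bayes_p: float | None = None
    converged: bool = False
    doublings_used: int = 0

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_species(self) -> int:
        return self.beta.shape[1]

    @property
    def q(self) -> int:
        return self.lam.shape[2]

    def chain_view(self, draws: np.ndarray) -> np.ndarray:
        """Reshape flattened draws back to (n_chains, draws_per_chain, ...)."""
        per = draws.shape[0] // self.n_chains
        return draws.reshape((self.n_chains, per) + draws.shape[1:])


def _free_loading_columns(i: int, q: int) -> np.ndarray:
    """Free columns of loading row i under the unit-lower-triangular constraint."""
    return np.arange(min(i, q))


def _prepare(arr: DetectionArray, X: np.ndarray):
    y = arr.y
    N, J, K = y.shape
    if X.shape[0] != J:
        raise ValueError("covariate rows must match number of sites")
    obs = arr.visits > 0
    if (y.sum(axis=(1, 2)) == 0).any():
        raise ValueError(
            "species with zero detections present; run detection.filter_species first"
        )
    det_any = (y > 0).any(axis=2)
    vu = np.unique(arr.visits[obs]).astype(float)  # distinct visit counts
    V = vu.size
    # C[j, g]: number of surveyed replicates at site j with visit count vu[g]
    C = np.zeros((J, V))
    for g, v in enumerate(vu):
        C[:, g] = ((arr.visits == v) & obs).sum(axis=1)
    # Y[i, g]: total detections of species i over cells in visit group g
    Y = np.zeros((N, V))
    for g, v in enumerate(vu):
        m = (arr.visits == v) & obs
        Y[:, g] = (y * m[None]).sum(axis=(1, 2))
    D = np.column_stack([np.ones(J), X])
    return D, obs, det_any, vu, C, Y


def _sample_mvn_batch(rng, A, b):
    """Draw from N(A^-1 b, A^-1) for a batch of small SPD matrices."""
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, b[..., None])[..., 0]
    eps = rng.standard_normal(b.shape)
    # solve L^T x = eps  =>  x ~ N(0, A^-1)
    x = np.linalg.solve(np.swapaxes(L, -1, -2), eps[..., None])[..., 0]
    return mean + x


def _run_chain_pg(rng, arr, D, obs, det_any, vu, C, Y, priors, st, keep):
    y = arr.y
    N, J, K = y.shape
    Pp1 = D.shape[1]
    q = st.q
    lv = priors.loading_prior_var

    beta = np.zeros((N, Pp1))
    alpha = np.zeros((N, 2))
    mu_b = np.zeros(Pp1)
    tau_b = np.ones(Pp1)
    mu_a = np.zeros(2)
    tau_a = np.ones(2)
    lam = np.zeros((N, q))
    for i in range(q):
        lam[i, i] = 1.0
    w = np.zeros((J, q))
    z = det_any.astype(float).copy()
    z[~det_any] = rng.random((~det_any).sum()) < 0.5

    out = {k: [] for k in (
        "beta", "alpha", "mu_beta", "tau_beta", "mu_alpha", "tau_alpha",
        "lam", "w", "z", "psi",
    )}
    free_cols = [_free_loading_columns(i, q) for i in range(N)]

    for it in range(st.n_samples):
        latent = lam @ w.T if q else 0.0  # (N, J)
        eta = beta @ D.T + latent
        omega = sample_pg(rng, eta)
        kappa = z - 0.5

        # species occupancy coefficients
        A = np.einsum("nj,jp,jq->npq", omega, D, D)
        A[:, np.arange(Pp1), np.arange(Pp1)] += 1.0 / tau_b
        resid = kappa - omega * latent if q else kappa
        b = resid @ D + mu_b / tau_b
        beta = _sample_mvn_batch(rng, A, b)
        xb = beta @ D.T  # (N, J)

        if q == 1:
            # single-factor fast path: every update is scalar-Gaussian
            wv = w[:, 0]
            prec = omega[1:] @ wv**2 + 1.0 / lv  # (N-1,)
            mean = (kappa[1:] - omega[1:] * xb[1:]) @ wv / prec
            lam[1:, 0] = mean + rng.standard_normal(N - 1) / np.sqrt(prec)
            lv0 = lam[:, 0]
            precw = omega.T @ lv0**2 + 1.0  # (J,)
            meanw = (kappa - omega * xb).T @ lv0 / precw
            w[:, 0] = meanw + rng.standard_normal(J) / np.sqrt(precw)
            latent = lam @ w.T
            eta = xb + latent
        elif q:
            # loadings (rows below the constrained block, plus free
            # lower-triangular entries inside it)
            for i in range(N):
                f = free_cols[i]
                if f.size == 0:
                    continue
                wf = w[:, f]
                fixed = lam[i].copy()
                fixed[f] = 0.0
                off = xb[i] + w @ fixed
                Ai = wf.T @ (omega[i, :, None] * wf) + np.eye(f.size) / lv
                bi = wf.T @ (kappa[i] - omega[i] * off)
                lam[i, f] = _sample_mvn_batch(rng, Ai[None], bi[None])[0]
            # latent factors, standard-normal prior
            Aw = np.einsum("nj,np,nq->jpq", omega, lam, lam)
            Aw[:, np.arange(q), np.arange(q)] += 1.0
            bw = np.einsum("nj,np->jp", kappa - omega * xb, lam)
            w = _sample_mvn_batch(rng, Aw, bw)
            latent = lam @ w.T
            eta = xb + latent
        else:
            eta = xb

        # latent presence where no detection pins z to one
        lp_det = alpha[:, 0, None] + alpha[:, 1, None] * vu[None, :]  # (N, V)
        log1mp = -np.logaddexp(0.0, lp_det)
        logodds = eta + log1mp @ C.T
        pz = expit(logodds)
        z = det_any.astype(float)
        free = ~det_any
        z[free] = (rng.random(int(free.sum())) < pz[free]).astype(float)

        # detection coefficients via grouped PG sums
        M = z @ C  # (N, V) cells at occupied sites per visit group
        Sw = np.zeros((N, len(vu)))
        pos = M > 0
        Sw[pos] = sample_pg_sum(rng, M[pos], lp_det[pos])
        k0 = (Y - M / 2.0).sum(axis=1) + mu_a[0] / tau_a[0]
        k1 = ((Y - M / 2.0) @ vu) + mu_a[1] / tau_a[1]
        s0 = Sw.sum(axis=1) + 1.0 / tau_a[0]
        s1 = Sw @ vu
        s2 = Sw @ vu**2 + 1.0 / tau_a[1]
        Aa = np.empty((N, 2, 2))
        Aa[:, 0, 0], Aa[:, 0, 1], Aa[:, 1, 0], Aa[:, 1, 1] = s0, s1, s1, s2
        alpha = _sample_mvn_batch(rng, Aa, np.column_stack([k0, k1]))

        mu_b, tau_b = _community_update(rng, beta, priors, tau_b)
        mu_a, tau_a = _community_update(rng, alpha, priors, tau_a)

        if it >= st.n_burn and (it - st.n_burn) % st.n_thin == 0 and keep:
            out["beta"].append(beta.copy())
            out["alpha"].append(alpha.copy())
            out["mu_beta"].append(mu_b.copy())
            out["tau_beta"].append(tau_b.copy())
            out["mu_alpha"].append(mu_a.copy())
            out["tau_alpha"].append(tau_a.copy())
            out["lam"].append(lam.copy())
            out["w"].append(w.copy())
            out["z"].append(z.astype(np.int8))
            out["psi"].append(expit(eta).astype(np.float32))
    return {k: np.array(v) for k, v in out.items()}


def _community_update(rng, coefs, priors, tau):
    """Conjugate two-block update: mu | tau, coefs then tau | mu, coefs."""
    N, P = coefs.shape
    var = 1.0 / (N / tau + 1.0 / priors.mu_var)
    mu = var * (coefs.sum(axis=0) / tau + priors.mu_mean / priors.mu_var)
    mu = mu + np.sqrt(var) * rng.standard_normal(P)
    sq = ((coefs - mu) ** 2).sum(axis=0)
    tau = 1.0 / rng.gamma(priors.ig_shape + N / 2.0, 1.0 / (priors.ig_scale + sq / 2.0))
    return mu, tau


def _run_chain_metropolis(rng, arr, D, obs, det_any, vu, C, Y, priors, st, keep):
    """Random-walk Metropolis-within-Gibbs variant (q = 0 cross-check)."""
    y = arr.y
    N, J, K = y.shape
    Pp1 = D.shape[1]

    beta = np.zeros((N, Pp1))
    alpha = np.zeros((N, 2))
    mu_b = np.zeros(Pp1)
    tau_b = np.ones(Pp1)
    mu_a = np.zeros(2)
    tau_a = np.ones(2)
    z = det_any.astype(float).copy()
    step_b = np.full(N, 0.3)
    step_a = np.full(N, 0.3)

    def occ_loglik(b, zz):
        eta = b @ D.T
        return (zz * eta - np.logaddexp(0.0, eta)).sum(axis=1)

    def det_loglik(a, M):
        lp = a[:, 0, None] + a[:, 1, None] * vu[None, :]
        return (Y * lp - M * np.logaddexp(0.0, lp)).sum(axis=1)

    out = {k: [] for k in (
        "beta", "alpha", "mu_beta", "tau_beta", "mu_alpha", "tau_alpha",
        "lam", "w", "z", "psi",
    )}
    for it in range(st.n_samples):
        prop = beta + step_b[:, None] * rng.standard_normal((N, Pp1))
        ll_new = occ_loglik(prop, z)
        ll_old = occ_loglik(beta, z)
        lpr = -(((prop - mu_b) ** 2 - (beta - mu_b) ** 2) / (2 * tau_b)).sum(axis=1)
        acc = np.log(rng.random(N)) < ll_new - ll_old + lpr
        beta[acc] = prop[acc]
        if it < st.n_burn:
            step_b *= np.where(acc, 1.05, 0.97)

        eta = beta @ D.T
        lp_det = alpha[:, 0, None] + alpha[:, 1, None] * vu[None, :]
        log1mp = -np.logaddexp(0.0, lp_det)
        pz = expit(eta + log1mp @ C.T)
        z = det_any.astype(float)
        freem = ~det_any
        z[freem] = (rng.random(int(freem.sum())) < pz[freem]).astype(float)

        M = z @ C
        prop = alpha + step_a[:, None] * rng.standard_normal((N, 2))
        ll_new = det_loglik(prop, M)
        ll_old = det_loglik(alpha, M)
        lpr = -(((prop - mu_a) ** 2 - (alpha - mu_a) ** 2) / (2 * tau_a)).sum(axis=1)
        acc = np.log(rng.random(N)) < ll_new - ll_old + lpr
        alpha[acc] = prop[acc]
        if it < st.n_burn:
            step_a *= np.where(acc, 1.05, 0.97)

        mu_b, tau_b = _community_update(rng, beta, priors, tau_b)
        mu_a, tau_a = _community_update(rng, alpha, priors, tau_a)

        if it >= st.n_burn and (it - st.n_burn) % st.n_thin == 0 and keep:
            out["beta"].append(beta.copy())
            out["alpha"].append(alpha.copy())
            out["mu_beta"].append(mu_b.copy())
            out["tau_beta"].append(tau_b.copy())
            out["mu_alpha"].append(mu_a.copy())
            out["tau_alpha"].append(tau_a.copy())
            out["lam"].append(np.zeros((N, 0)))
            out["w"].append(np.zeros((J, 0)))
            out["z"].append(z.astype(np.int8))
            out["psi"].append(expit(eta).astype(np.float32))
    return {k: np.array(v) for k, v in out.items()}


def _monitored(chains: list[dict]) -> dict[str, np.ndarray]:
    """Community means/variances and species coefficients as (C, S) series."""
    series = {}
    C = len(chains)
    for name in ("mu_beta", "tau_beta", "mu_alpha", "tau_alpha"):
        x = np.stack([ch[name] for ch in chains])  # (C, S, P)
        for p in range(x.shape[2]):
            series[f"{name}[{p}]"] = x[:, :, p]
    for name in ("beta", "alpha"):
        x = np.stack([ch[name] for ch in chains])  # (C, S, N, P)
        for i in range(x.shape[2]):
            for p in range(x.shape[3]):
                series[f"{name}[{i},{p}]"] = x[:, :, i, p]
    return series


def fit(
    arr: DetectionArray,
    X: np.ndarray,
    priors: PriorSpec | None = None,
    settings: McmcSettings | None = None,
) -> Posterior:
    """Fit an MSO (q=0) or LFMSO (q>=1) model to detection histories.

    ``X`` must already be z-scored (see :func:`odorare.detection.standardize`).
    Returns a :class:`Posterior` with convergence diagnostics on the
    community parameters and all species coefficients, and the run's WAIC.
    """
    priors = priors or PriorSpec()
    st = settings or McmcSettings()
    X = np.asarray(X, dtype=float)
    if st.q >= arr.n_species:
        raise ValueError("q must be smaller than the number of species")
    D, obs, det_any, vu, C, Y = _prepare(arr, X)
    runner = _run_chain_pg if st.algorithm == "pg" else _run_chain_metropolis

    doublings = 0
    while True:
        chains = []
        for c in range(st.n_chains):
            rng = np.random.default_rng([st.seed, doublings, c])
            chains.append(
                runner(rng, arr, D, obs, det_any, vu, C, Y, priors, st, keep=True)
            )
        series = _monitored(chains)
        rhat = {k: compute_rhat(v) for k, v in series.items()} if st.n_chains > 1 else {}
        ess = {k: compute_ess(v) for k, v in series.items()} if st.n_chains > 1 else {}
        converged = all(r < 1.1 for r in rhat.values()) and all(
            e > 100 for e in ess.values()
        ) if rhat else True
        if converged or doublings >= st.max_doublings:
            break
        st = st.doubled()
        doublings += 1

    post = Posterior(
        beta=np.concatenate([c["beta"] for c in chains]),
        alpha=np.concatenate([c["alpha"] for c in chains]),
        mu_beta=np.concatenate([c["mu_beta"] for c in chains]),
        tau_beta=np.concatenate([c["tau_beta"] for c in chains]),
        mu_alpha=np.concatenate([c["mu_alpha"] for c in chains]),
        tau_alpha=np.concatenate([c["tau_alpha"] for c in chains]),
        lam=np.concatenate([c["lam"] for c in chains]),
        w=np.concatenate([c["w"] for c in chains]),
        z=np.concatenate([c["z"] for c in chains]),
        psi=np.concatenate([c["psi"] for c in chains]),
        n_chains=st.n_chains,
        rhat=rhat,
        ess=ess,
        converged=converged,
        doublings_used=doublings,
    )
    post.waic = compute_waic(post, arr)
    return post


def goodness_of_fit(post: Posterior, arr: DetectionArray, seed: int = 0) -> float:
    """Posterior-predictive Bayesian p-value (site-grouped chi-square)."""
    post.bayes_p = bayes_p_value(post, arr, seed=seed)
    return post.bayes_p


def predict_occupancy(
    post: Posterior, X_new: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior occupancy surface at new sites.

    Latent factors at unfitted sites have no posterior, so they are
    marginalized by drawing w_new ~ N(0, 1) per posterior draw; X_new must
    be standardized with the training means/sds.  Returns (posterior-mean
    psi (N, J_new), psi draws (S, N, J_new))."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    Pp1 = post.beta.shape[2]
    if X_new.shape[1] != Pp1 - 1:
        raise ValueError("X_new column count does not match training covariates")
    rng = np.random.default_rng(seed)
    Dn = np.column_stack([np.ones(X_new.shape[0]), X_new])
    eta = np.einsum("snp,jp->snj", post.beta, Dn)
    if post.q:
        w_new = rng.standard_normal((post.n_draws, post.q, X_new.shape[0]))
        eta += np.einsum("snq,sqj->snj", post.lam, w_new)
    draws = expit(eta)
    return draws.mean(axis=0), draws


def predict_richness(post: Posterior) -> np.ndarray:
    """Posterior-mean species richness per fitted site: E[sum_i z_ij]."""
    return post.z.sum(axis=1).mean(axis=0)


def meaningful_factors(post: Posterior, level: float = 0.95) -> list[int]:
    """Factors with at least one sign-consistent, non-null loading.

    A factor is reported as meaningful when some free loading's credible
    interval at ``level`` excludes zero in every chain with the same sign —
    the working rule for deciding how many latent factors carry signal.
    """
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    kept = []
    lam_chains = post.chain_view(post.lam)  # (C, S, N, q)
    for f in range(post.q):
        for i in range(post.beta.shape[1]):
            if i <= f:
                continue  # constrained block rows
            lo = np.quantile(lam_chains[:, :, i, f], lo_q, axis=1)
            hi = np.quantile(lam_chains[:, :, i, f], hi_q, axis=1)
            if (lo > 0).all() or (hi < 0).all():
                kept.append(f)
                break
    return kept
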