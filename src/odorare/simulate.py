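"""Synthetic replicated-survey communities for occupancy modelling.

Generates detection/non-detection data with the exact hierarchy the
multispecies occupancy models assume: species-level occupancy coefficients
drawn from community-level normal distributions, an optional single latent
site factor with species loadings, a Bernoulli presence state per
species x site, and imperfect replicate-level detection driven by a
visit-count covariate.  A degradation step emulates real survey pathologies
(species recorded too rarely to model, sites with down-weighted effort) so
the data-deficient paths of the rarity engine are exercisable end to end.

Community-scale defaults follow the magnitudes reported for a national
freshwater-insect survey: occupancy slopes of order +-0.5 on z-scored
covariates, a detection intercept near -1 with a positive visit-count
effect, and a mean of three visits per replicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit


@dataclass
class CommunityConfig:
    """Generating parameters for a synthetic survey community.

    ``mu_beta``/``tau_beta`` are the community mean and variance of the
    species occupancy coefficients (intercept + P slopes, logit scale);
    ``mu_alpha``/``tau_alpha`` the same for detection (intercept, visit
    slope).  ``q_true`` switches the latent site factor on (1) or off (0).
    """

    N: int = 20
    J: int = 200
    K: int = 4
    P: int = 3
    q_true: int = 1
    mu_beta: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.5, -0.5, 0.3]))
    tau_beta: np.ndarray = field(default_factory=lambda: np.full(4, 0.5))
    mu_alpha: np.ndarray = field(default_factory=lambda: np.array([-1.0, 0.25]))
    tau_alpha: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.05]))
    lambda_scale: float = 1.0
    visit_rate: float = 3.0
    spatial_blur: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu_beta = np.asarray(self.mu_beta, dtype=float)
        self.tau_beta = np.asarray(self.tau_beta, dtype=float)
        self.mu_alpha = np.asarray(self.mu_alpha, dtype=float)
        self.tau_alpha = np.asarray(self.tau_alpha, dtype=float)
        if min(self.N, self.J, self.K) < 1:
            raise ValueError("N, J and K must all be >= 1")
        if self.q_true not in (0, 1):
            raise ValueError("q_true must be 0 or 1")
        if self.mu_beta.shape != (self.P + 1,) or self.tau_beta.shape != (self.P + 1,):
            raise ValueError("mu_beta/tau_beta must have length P+1")
        if self.mu_alpha.shape != (2,) or self.tau_alpha.shape != (2,):
            raise ValueError("mu_alpha/tau_alpha must have length 2")
        if np.any(self.tau_beta <= 0) or np.any(self.tau_alpha <= 0):
            raise ValueError("community variances must be positive")
        if self.visit_rate < 1:
            raise ValueError("visit_rate must be >= 1 (every replicate is surveyed)")


@dataclass
class SyntheticDataset:
    """A generated community with full generating truth attached."""

    y: np.ndarray  # (N, J, K) binary detections
    z_true: np.ndarray  # (N, J) latent presence
    psi_true: np.ndarray  # (N, J) occupancy probabilities
    X: np.ndarray  # (J, P) z-scored site covariates
    visits: np.ndarray  # (J, K) visit counts, all >= 1
    beta_true: np.ndarray  # (N, P+1)
    alpha_true: np.ndarray  # (N, 2)
    lambda_true: np.ndarray  # (N, q_true)
    w_true: np.ndarray  # (J, q_true)
    coords: np.ndarray  # (J, 2) integer 1-km grid indices
    species_names: list[str]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.y.shape


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0)


def simulate_community(config: CommunityConfig) -> SyntheticDataset:
    """Run the occupancy hierarchy generatively.

    Species coefficients beta_i ~ N(mu_beta, diag(tau_beta)) and
    alpha_i ~ N(mu_alpha, diag(tau_alpha)); logit psi = X beta + lambda w
    with w_j ~ N(0,1); z ~ Bernoulli(psi); detection per replicate
    y ~ Bernoulli(z * p) with logit p = alpha0 + alpha1 * visits.  The
    loading of the first species is pinned to 1 (the same lower-triangular
    unit-diagonal convention the fitter uses), so simulated loadings are
    directly comparable with posterior ones.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    side = int(np.ceil(np.sqrt(cfg.J)))
    cells = np.array([(i % side, i // side) for i in range(cfg.J)], dtype=int)

    X = rng.standard_normal((cfg.J, cfg.P))
    if cfg.spatial_blur > 0:
        # impose spatial autocorrelation by smoothing covariates on the grid
        grid = np.full((side, side, cfg.P), np.nan)
        grid[cells[:, 1], cells[:, 0]] = X
        np.nan_to_num(grid, copy=False)
        for p in range(cfg.P):
            grid[:, :, p] = gaussian_filter(grid[:, :, p], cfg.spatial_blur)
        X = grid[cells[:, 1], cells[:, 0]]
    X = _standardize_columns(X)

    beta = cfg.mu_beta + np.sqrt(cfg.tau_beta) * rng.standard_normal((cfg.N, cfg.P + 1))
    alpha = cfg.mu_alpha + np.sqrt(cfg.tau_alpha) * rng.standard_normal((cfg.N, 2))

    if cfg.q_true == 1:
        lam = cfg.lambda_scale * rng.standard_normal((cfg.N, 1))
        lam[0, 0] = 1.0  # identifiability anchor
        w = rng.standard_normal((cfg.J, 1))
        latent = lam @ w.T  # (N, J)
    else:
        lam = np.zeros((cfg.N, 0))
        w = np.zeros((cfg.J, 0))
        latent = 0.0

    design = np.column_stack([np.ones(cfg.J), X])  # (J, P+1)
    eta = beta @ design.T + latent  # (N, J)
    psi = expit(eta)
    z = (rng.random((cfg.N, cfg.J)) < psi).astype(np.int8)

    visits = 1 + rng.poisson(cfg.visit_rate - 1.0, size=(cfg.J, cfg.K))
    logit_p = alpha[:, 0, None, None] + alpha[:, 1, None, None] * visits[None, :, :]
    p = expit(logit_p)  # (N, J, K)
    y = (rng.random((cfg.N, cfg.J, cfg.K)) < p * z[:, :, None]).astype(np.int8)

    names = [f"sp{i:03d}" for i in range(cfg.N)]
    return SyntheticDataset(
        y=y, z_true=z, psi_true=psi, X=X, visits=visits,
        beta_true=beta, alpha_true=alpha, lambda_true=lam, w_true=w,
        coords=cells, species_names=names,
    )


def degrade_to_survey(
    dataset: SyntheticDataset,
    species_dropout: float = 0.0,
    lotic_bias: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Emulate survey pathologies on a clean simulated community.

    A ``species_dropout`` fraction of species keeps at most two randomly
    chosen detections (everything else masked to non-detection), producing
    species that fall below the modelling filter and must be routed to the
    data-deficient status.  A ``lotic_bias`` fraction of sites gets its
    visit counts halved (floored at one visit), mimicking effort
    concentrated away from part of the landscape.  Truth arrays are left
    untouched; only ``y`` and ``visits`` change.
    """
    if not (0 <= species_dropout <= 1 and 0 <= lotic_bias <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    y = dataset.y.copy()
    visits = dataset.visits.copy()
    N, J, K = y.shape

    n_drop = int(round(species_dropout * N))
    if n_drop:
        dropped = rng.choice(N, size=n_drop, replace=False)
        for i in dropped:
            pos = np.argwhere(y[i] == 1)
            if len(pos) > 2:
                keep = rng.choice(len(pos), size=2, replace=False)
                mask = np.ones(len(pos), dtype=bool)
                mask[keep] = False
                for j, k in pos[mask]:
                    y[i, j, k] = 0

    n_bias = int(round(lotic_bias * J))
    if n_bias:
        biased = rng.choice(J, size=n_bias, replace=False)
        visits[biased] = np.maximum(1, visits[biased] // 2)

    return replace(dataset, y=y, visits=visits)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write a dataset directory: y.csv (long), sites.csv, truth.json."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    N, J, K = dataset.y.shape
    ii, jj, kk = np.nonzero(np.ones_like(dataset.y))
    pd.DataFrame(
        {
            "species": [dataset.species_names[i] for i in ii],
            "site": jj,
            "replicate": kk,
            "detected": dataset.y[ii, jj, kk],
        }
    ).to_csv(out / "y.csv", index=False)

    site_df = pd.DataFrame(dataset.X, columns=[f"cov{p}" for p in range(dataset.X.shape[1])])
    site_df.insert(0, "site", np.arange(J))
    site_df.insert(1, "x", dataset.coords[:, 0])
    site_df.insert(2, "y", dataset.coords[:, 1])
    for k in range(K):
        site_df[f"visits_r{k}"] = dataset.visits[:, k]
    site_df.to_csv(out / "sites.csv", index=False)

    truth = {
        "beta_true": dataset.beta_true.tolist(),
        "alpha_true": dataset.alpha_true.tolist(),
        "lambda_true": dataset.lambda_true.tolist(),
        "w_true": dataset.w_true.tolist(),
        "psi_true": dataset.psi_true.tolist(),
        "z_true": dataset.z_true.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(truth))
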