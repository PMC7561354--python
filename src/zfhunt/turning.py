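"""Bayesian linear regression of first-turn magnitude on prey azimuth.

The first turn phi (degrees) toward a prey at azimuth theta (degrees) is
modelled as phi ~ Normal(beta0 + beta1 * theta, sigma^2).  The slope beta1
is the group turn-ratio: beta1 < 1 means the group undershoots the prey's
bearing.  Priors (Normal distributions parametrized by precision):

    sigma^2 ~ InvGamma(5, 2)
    beta0   ~ Normal(0, precision 2)
    beta1   ~ Normal(0, precision t1),  t1 ~ Gamma(1, 1)

The model is fully conditionally conjugate, so the posterior is sampled by
Gibbs: a bivariate normal update for (beta0, beta1), an inverse-gamma
update for sigma^2 and a gamma update for the slope's hyper-precision t1.
Events are pooled across larvae within one group (this reproduces the
pooling of the original per-event analysis, which can be biased toward
more active individuals; the unbiased per-larva version lives in
:mod:`zfhunt.groups`).
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import gaussian_kde

from .samplers import (
    DEFAULT_CHAINS,
    DEFAULT_DRAWS,
    DEFAULT_WARMUP,
    PosteriorSamples,
)

__all__ = ["fit_turn_model", "undershoot_probability", "slope_density"]

# priors as printed (precision parametrization for normals)
SIGMA2_SHAPE, SIGMA2_RATE = 5.0, 2.0
BETA0_PRECISION = 2.0
T1_SHAPE, T1_RATE = 1.0, 1.0


def fit_turn_model(
    theta_deg: Sequence[float],
    phi_deg: Sequence[float],
    *,
    n_chains: int = DEFAULT_CHAINS,
    n_draws: int = DEFAULT_DRAWS,
    n_warmup: int = DEFAULT_WARMUP,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Posterior over (beta0, beta1, sigma2) for pooled (theta, phi) pairs."""
    theta = np.asarray(theta_deg, dtype=float)
    phi = np.asarray(phi_deg, dtype=float)
    if theta.shape != phi.shape or theta.ndim != 1:
        raise ValueError("theta and phi must be 1-D and aligned")
    n = len(theta)
    if n < 5:
        raise ValueError("need at least 5 events to fit the turn model")
    if np.ptp(theta) == 0:
        raise ValueError("all azimuths identical: design matrix is rank deficient")
    rng = rng if rng is not None else np.random.default_rng(seed)

    X = np.column_stack([np.ones(n), theta])
    XtX = X.T @ X
    Xty = X.T @ phi

    b0 = np.zeros((n_chains, n_draws))
    b1 = np.zeros((n_chains, n_draws))
    s2 = np.zeros((n_chains, n_draws))

    for c in range(n_chains):
        beta = np.array([0.0, 1.0]) + 0.1 * rng.standard_normal(2)
        sigma2 = 100.0 * (1 + rng.uniform())
        t1 = 1.0
        for it in range(n_warmup + n_draws):
            # (beta0, beta1) | sigma2, t1 : bivariate normal
            prec = XtX / sigma2 + np.diag([BETA0_PRECISION, t1])
            cov = np.linalg.inv(prec)
            mean = cov @ (Xty / sigma2)
            beta = rng.multivariate_normal(mean, cov, method="cholesky")
            # sigma2 | beta : inverse gamma
            resid = phi - X @ beta
            sigma2 = 1.0 / rng.gamma(
                SIGMA2_SHAPE + 0.5 * n, 1.0 / (SIGMA2_RATE + 0.5 * resid @ resid)
            )
            # t1 | beta1 : gamma
            t1 = rng.gamma(T1_SHAPE + 0.5, 1.0 / (T1_RATE + 0.5 * beta[1] ** 2))
            if it >= n_warmup:
                b0[c, it - n_warmup] = beta[0]
                b1[c, it - n_warmup] = beta[1]
                s2[c, it - n_warmup] = sigma2

    return PosteriorSamples({"beta0": b0, "beta1": b1, "sigma2": s2})


def undershoot_probability(fit: PosteriorSamples) -> float:
    """Posterior probability that the turn-ratio slope is below unity."""
    return float(np.mean(fit.get("beta1") < 1.0))


def slope_density(
    fit: PosteriorSamples, bandwidth: float = 0.01, grid: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of the slope draws (absolute bandwidth 0.01)."""
    draws = fit.get("beta1")
    if grid is None:
        lo, hi = draws.min() - 5 * bandwidth, draws.max() + 5 * bandwidth
        grid = np.linspace(lo, hi, 512)
    kde = gaussian_kde(draws, bw_method=bandwidth / draws.std(ddof=1))
    return grid, kde(grid)
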