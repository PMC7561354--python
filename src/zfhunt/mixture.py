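"""Two-component bivariate Gaussian mixture over (capture speed, prey distance).

Successful capture swims divide into a slow, short-range type and a fast,
longer-range lunge.  Each point (s_i, d_i) carries a latent label
c_i in {slow, fast} with a per-point prior of 0.5, and each cluster is a
full bivariate normal with its own means, standard deviations and
speed-distance correlation.  Priors (Normal(mean, precision) notation):

    mu_s(slow) ~ N(5,  0.01)     mu_s(fast) ~ N(35, 0.01)
    mu_d       ~ N(0.5, 10)      (both clusters)
    sigma_s(slow) ~ U(0, 2)      sigma_s(fast) ~ U(0, 10)
    sigma_d ~ U(0, 1)            rho ~ U(-1, 1)

The narrow slow-speed sigma encodes that slow captures sit in a tight band
at the bottom of the speed range, while fast captures spread widely.  The
mixture is sampled by Gibbs (exact label and conjugate mean updates,
random-walk Metropolis on the covariance parameters) with the fast cluster
identified by the larger mean speed in every draw.  A point is labelled a
fast capture swim when its expected membership E[c] exceeds 0.7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .samplers import (
    DEFAULT_CHAINS,
    DEFAULT_DRAWS,
    DEFAULT_WARMUP,
    PosteriorSamples,
)

__all__ = [
    "MixtureFit",
    "fit_capture_mixture",
    "membership_given_params",
    "speed_distance_correlation",
    "FAST_MEMBERSHIP_THRESHOLD",
]

logger = logging.getLogger(__name__)

FAST_MEMBERSHIP_THRESHOLD = 0.7
P_FAST_DENSITY_SD = 0.03
CLUSTER_PRIOR_FAST = 0.5  # per-point label prior

# prior constants: (mean-prior mean, mean-prior precision) and sigma bounds
PRIORS = {
    "slow": {"mu_s": (5.0, 0.01), "mu_d": (0.5, 10.0), "sigma_s_max": 2.0, "sigma_d_max": 1.0},
    "fast": {"mu_s": (35.0, 0.01), "mu_d": (0.5, 10.0), "sigma_s_max": 10.0, "sigma_d_max": 1.0},
}


def _bvn_logpdf(x: np.ndarray, mu: np.ndarray, sig: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate normal log density, vectorized over rows of x."""
    z1 = (x[:, 0] - mu[0]) / sig[0]
    z2 = (x[:, 1] - mu[1]) / sig[1]
    om = 1.0 - rho**2
    return (
        -np.log(2 * np.pi * sig[0] * sig[1] * np.sqrt(om))
        - (z1**2 - 2 * rho * z1 * z2 + z2**2) / (2 * om)
    )


def membership_given_params(
    points: np.ndarray, params: Dict[str, Dict[str, float]], p_fast_prior: float = CLUSTER_PRIOR_FAST
) -> np.ndarray:
    """P(fast | point) under FIXED cluster parameters.

    ``params`` maps 'slow'/'fast' to dicts with mu_s, mu_d, sigma_s,
    sigma_d, rho.  This is the quantity the Gibbs label step draws from; it
    is checked against a brute-force label-assignment enumeration in the
    test suite.
    """
    x = np.asarray(points, dtype=float)
    lp = {}
    for c in ("slow", "fast"):
        p = params[c]
        lp[c] = _bvn_logpdf(
            x, np.array([p["mu_s"], p["mu_d"]]), np.array([p["sigma_s"], p["sigma_d"]]), p["rho"]
        )
    lf = np.log(p_fast_prior) + lp["fast"]
    ls = np.log1p(-p_fast_prior) + lp["slow"]
    m = np.maximum(lf, ls)
    return np.exp(lf - m) / (np.exp(lf - m) + np.exp(ls - m))


@dataclass
class MixtureFit:
    """Posterior draws, per-point memberships and the fast/slow labelling."""

    posterior: PosteriorSamples
    membership: np.ndarray  # per-point E[c], c=1 for fast
    labels: np.ndarray  # 'fast' where E[c] > threshold, else 'slow'
    p_fast: float  # fraction of points labelled fast
    threshold: float = FAST_MEMBERSHIP_THRESHOLD

    def p_fast_density(self, grid: np.ndarray) -> np.ndarray:
        """Smoothed density of the fast fraction: Normal(p_fast, 0.03)."""
        return np.exp(-0.5 * ((grid - self.p_fast) / P_FAST_DENSITY_SD) ** 2) / (
            P_FAST_DENSITY_SD * np.sqrt(2 * np.pi)
        )


def fit_capture_mixture(
    points: np.ndarray,
    *,
    n_chains: int = DEFAULT_CHAINS,
    n_draws: int = DEFAULT_DRAWS,
    n_warmup: int = DEFAULT_WARMUP,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    threshold: float = FAST_MEMBERSHIP_THRESHOLD,
    speed_mean_precision: float = 0.01,
) -> MixtureFit:
    """Fit the two-cluster mixture to (speed, distance) points by Gibbs/MH."""
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (speed, distance)")
    n = len(x)
    if n < 10:
        raise ValueError("mixture fit refused: need at least 10 points")
    if np.any(x < 0):
        raise ValueError("speeds and distances must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)

    names = ["mu_s", "mu_d", "sigma_s", "sigma_d", "rho"]
    store = {
        f"{p}_{c}": np.zeros((n_chains, n_draws)) for c in ("slow", "fast") for p in names
    }
    memb_sum = np.zeros(n)

    for chain in range(n_chains):
        # initial state from the priors' centres, perturbed per chain
        state = {
            "slow": {
                "mu": np.array([5.0, 0.3]) * (1 + 0.1 * rng.standard_normal(2)),
                "sig": np.array([1.0, 0.1]),
                "rho": 0.0,
            },
            "fast": {
                "mu": np.array([35.0, 0.4]) * (1 + 0.1 * rng.standard_normal(2)),
                "sig": np.array([5.0, 0.1]),
                "rho": 0.0,
            },
        }
        steps = {"slow": np.array([0.2, 0.02, 0.08]), "fast": np.array([1.0, 0.02, 0.08])}
        scale = {"slow": 1.0, "fast": 1.0}

        for it in range(n_warmup + n_draws):
            # --- labels | params (exact) ---------------------------------
            params = {
                c: {
                    "mu_s": state[c]["mu"][0],
                    "mu_d": state[c]["mu"][1],
                    "sigma_s": state[c]["sig"][0],
                    "sigma_d": state[c]["sig"][1],
                    "rho": state[c]["rho"],
                }
                for c in ("slow", "fast")
            }
            pf = membership_given_params(x, params)
            fast = rng.uniform(size=n) < pf

            # --- cluster means | labels, covariances (conjugate) ---------
            new_mu = {}
            for c, mask in (("slow", ~fast), ("fast", fast)):
                m0 = np.array([PRIORS[c]["mu_s"][0], PRIORS[c]["mu_d"][0]])
                prec0 = np.diag([speed_mean_precision, PRIORS[c]["mu_d"][1]])
                sig, rho = state[c]["sig"], state[c]["rho"]
                cov_c = np.array(
                    [
                        [sig[0] ** 2, rho * sig[0] * sig[1]],
                        [rho * sig[0] * sig[1], sig[1] ** 2],
                    ]
                )
                prec_c = np.linalg.inv(cov_c)
                k = int(mask.sum())
                post_prec = prec0 + k * prec_c
                post_cov = np.linalg.inv(post_prec)
                xbar = x[mask].sum(axis=0)
                post_mean = post_cov @ (prec0 @ m0 + prec_c @ xbar)
                new_mu[c] = rng.multivariate_normal(post_mean, post_cov, method="cholesky")
            # ordering constraint: fast cluster keeps the larger mean speed
            if new_mu["fast"][0] > new_mu["slow"][0]:
                state["slow"]["mu"], state["fast"]["mu"] = new_mu["slow"], new_mu["fast"]

            # --- covariance params | labels, means (Metropolis) ----------
            for c, mask in (("slow", ~fast), ("fast", fast)):
                xc = x[mask]
                cur = np.array([*state[c]["sig"], state[c]["rho"]])
                prop = cur + scale[c] * steps[c] * rng.standard_normal(3)
                ok = (
                    0 < prop[0] < PRIORS[c]["sigma_s_max"]
                    and 0 < prop[1] < PRIORS[c]["sigma_d_max"]
                    and -1 < prop[2] < 1
                )
                accepted = False
                if ok:
                    if len(xc):
                        ll_cur = _bvn_logpdf(xc, state[c]["mu"], cur[:2], cur[2]).sum()
                        ll_prop = _bvn_logpdf(xc, state[c]["mu"], prop[:2], prop[2]).sum()
                    else:
                        ll_cur = ll_prop = 0.0
                    if np.log(rng.uniform()) < ll_prop - ll_cur:
                        state[c]["sig"] = prop[:2]
                        state[c]["rho"] = prop[2]
                        accepted = True
                if it < n_warmup:
                    gamma = 1.0 / (1 + it) ** 0.6
                    scale[c] *= float(np.exp(gamma * (accepted - 0.3)))

            if it >= n_warmup:
                j = it - n_warmup
                for c in ("slow", "fast"):
                    store[f"mu_s_{c}"][chain, j] = state[c]["mu"][0]
                    store[f"mu_d_{c}"][chain, j] = state[c]["mu"][1]
                    store[f"sigma_s_{c}"][chain, j] = state[c]["sig"][0]
                    store[f"sigma_d_{c}"][chain, j] = state[c]["sig"][1]
                    store[f"rho_{c}"][chain, j] = state[c]["rho"]
                memb_sum += fast

    membership = memb_sum / (n_chains * n_draws)
    labels = np.where(membership > threshold, "fast", "slow")
    p_fast = float(np.mean(labels == "fast"))
    return MixtureFit(
        posterior=PosteriorSamples(store),
        membership=membership,
        labels=labels,
        p_fast=p_fast,
        threshold=threshold,
    )


def speed_distance_correlation(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    frac: float = 0.8,
    method: str = "pearson",
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> np.ndarray:
    """Bootstrap distribution of the correlation between two pooled variables.

    Each of ``n_boot`` coefficients is computed on a random 80% subsample
    drawn without replacement.  ``method`` is 'pearson' (speed vs distance)
    or 'spearman' (time-to-prey vs distance; turn-ratio vs speed).
    Subsamples with a constant column are skipped with a notice.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be aligned 1-D arrays")
    if len(x) < 10:
        raise ValueError("need at least 10 points")
    corr = pearsonr if method == "pearson" else spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    rng = rng if rng is not None else np.random.default_rng(seed)
    k = max(2, int(round(frac * len(x))))
    out = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.choice(len(x), size=k, replace=False)
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
            skipped += 1
            continue
        out.append(corr(x[idx], y[idx])[0])
    if skipped:
        logger.info("skipped %d bootstrap subsamples with a constant column", skipped)
    return np.asarray(out)
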