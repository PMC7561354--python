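"""Hierarchical multivariate-normal model of per-larva mean hunting behavior.

Pooling hunt events across larvae biases group estimates toward the most
active individuals.  This model removes that bias with two levels: events
(capture speed mm/s, capture distance mm, turn-ratio) are MVN around a
per-larva mean vector, and larva means are MVN around the group mean.
Larvae contributing a single event are handled by partial pooling.

    x_ij ~ MVN(m_i, Sigma_w)         (events j of larva i)
    m_i  ~ MVN(mu_g, Sigma_b)        (larva means)

Priors (weakly informative, scaled to the data):

    mu_g    ~ MVN(column medians, diag((10 * column sd)^2))
    Sigma_* = D(sigma) R D(sigma); sigma_k ~ HalfNormal(5 * column sd_k),
              R uniform over valid correlation matrices

The within-larva covariance is shared across larvae.  Sampling is a
collapsed Gibbs scheme: the larva means are integrated out analytically
(xbar_i ~ MVN(mu_g, Sigma_b + Sigma_w / n_i) plus a pooled-scatter term),
mu_g is then conjugate, and the covariance parameters (log-scales plus
correlations, rejected when not positive definite) move by componentwise
adaptive Metropolis on the collapsed likelihood.  Collapsing removes the
funnel between Sigma_b and the larva means, which otherwise mixes poorly;
larva means are re-drawn conjugately for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .samplers import (
    DEFAULT_CHAINS,
    DEFAULT_DRAWS,
    DEFAULT_WARMUP,
    PosteriorSamples,
    prob_greater,
)

__all__ = ["GroupPosterior", "fit_group_model", "group_comparison", "COMPONENTS"]

COMPONENTS = ("speed", "distance", "turn_ratio")
EVENT_COLUMNS = ("capture_speed_mm_s", "capture_distance_mm", "turn_ratio")


@dataclass
class GroupPosterior:
    """Posterior draws for one group's hierarchical fit."""

    posterior: PosteriorSamples  # mu_speed, mu_distance, mu_turn_ratio + scales
    larva_ids: list
    larva_mean_draws: np.ndarray  # (n_chains*n_draws, n_larvae, 3)

    def mu_draws(self) -> np.ndarray:
        """Group-mean draws as an (n_total, 3) array in COMPONENTS order."""
        return np.column_stack([self.posterior.get(f"mu_{c}") for c in COMPONENTS])

    def larva_posterior_means(self) -> pd.DataFrame:
        m = self.larva_mean_draws.mean(axis=0)
        return pd.DataFrame(m, columns=list(EVENT_COLUMNS)).assign(larva_id=self.larva_ids)


def _corr_from_params(r: np.ndarray) -> Optional[np.ndarray]:
    """3x3 correlation matrix from (r12, r13, r23); None if not PD."""
    if np.any(np.abs(r) >= 1):
        return None
    R = np.array([[1, r[0], r[1]], [r[0], 1, r[2]], [r[1], r[2], 1.0]])
    if np.linalg.eigvalsh(R).min() <= 1e-10:
        return None
    return R


def _cov(log_sig: np.ndarray, r: np.ndarray) -> Optional[np.ndarray]:
    R = _corr_from_params(r)
    if R is None:
        return None
    s = np.exp(log_sig)
    return R * np.outer(s, s)


def _mvn_logpdf_sum(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Sum of MVN log densities of rows of x (mean may be per-row)."""
    L = np.linalg.cholesky(cov)
    d = x - mean
    z = np.linalg.solve(L, d.T)
    quad = np.sum(z**2)
    n, k = x.shape
    return -0.5 * quad - n * (np.sum(np.log(np.diag(L))) + 0.5 * k * np.log(2 * np.pi))


def fit_group_model(
    events: pd.DataFrame,
    *,
    n_chains: int = DEFAULT_CHAINS,
    n_draws: int = DEFAULT_DRAWS,
    n_warmup: int = DEFAULT_WARMUP,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    fixed_cov: Optional[tuple] = None,
) -> GroupPosterior:
    """Fit the two-level model to per-event rows tagged by ``larva_id``.

    ``events`` needs columns larva_id, capture_speed_mm_s,
    capture_distance_mm, turn_ratio; rows with any missing feature are
    dropped listwise.  Requires at least 3 larvae with one event each.

    ``fixed_cov=(cov_w, cov_b)`` pins both covariance matrices (no MH
    updates); in that case the group-mean posterior is exactly conjugate,
    which the test suite exploits as a closed-form oracle.
    """
    df = events.dropna(subset=list(EVENT_COLUMNS))
    groups = df.groupby("larva_id", sort=True)
    larva_ids = list(groups.groups)
    n_larvae = len(larva_ids)
    if n_larvae < 3:
        raise ValueError("group model refused: need at least 3 larvae with events")
    rng = rng if rng is not None else np.random.default_rng(seed)

    X = [groups.get_group(i)[list(EVENT_COLUMNS)].to_numpy(dtype=float) for i in larva_ids]
    counts = np.array([len(x) for x in X])
    sums = np.vstack([x.sum(axis=0) for x in X])
    xbar = sums / counts[:, None]
    allx = np.vstack(X)
    # pooled within-larva deviation scatter (sufficient statistic for Sigma_w)
    scatter = np.zeros((3, 3))
    for x, xb in zip(X, xbar):
        d = x - xb
        scatter += d.T @ d
    n_events_total = len(allx)

    col_sd = np.maximum(allx.std(axis=0, ddof=1), 1e-3)
    prior_mean = np.median(allx, axis=0)
    prior_prec = np.diag(1.0 / (10.0 * col_sd) ** 2)
    half_normal_scale = 5.0 * col_sd

    keep = {
        **{f"mu_{c}": np.zeros((n_chains, n_draws)) for c in COMPONENTS},
        **{f"sigma_b_{c}": np.zeros((n_chains, n_draws)) for c in COMPONENTS},
        **{f"sigma_w_{c}": np.zeros((n_chains, n_draws)) for c in COMPONENTS},
    }
    thin = max(1, n_draws // 200)  # larva-mean draws are memory-heavy; thin them
    larva_keep = []

    uniq_counts = np.unique(counts)
    idx_by_count = {int(n): np.flatnonzero(counts == n) for n in uniq_counts}
    group_sizes = np.array([len(idx_by_count[int(n)]) for n in uniq_counts])
    # xbar rows reordered so larvae sharing an event count are contiguous
    order = np.concatenate([idx_by_count[int(n)] for n in uniq_counts])
    xbar_sorted = xbar[order]
    group_of_larva = np.repeat(np.arange(len(uniq_counts)), group_sizes)
    ln2pi = np.log(2 * np.pi)

    def marginal_ll(mu: np.ndarray, cov_w: np.ndarray, cov_b: np.ndarray) -> float:
        """Log likelihood with larva means integrated out (collapsed).

        xbar_i ~ MVN(mu, cov_b + cov_w / n_i); the within-larva deviations
        contribute through the pooled scatter matrix.
        """
        Vs = cov_b[None, :, :] + cov_w[None, :, :] / uniq_counts[:, None, None]
        try:
            Ls = np.linalg.cholesky(Vs)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet_half = np.log(np.diagonal(Ls, axis1=1, axis2=2)).sum(axis=1)
        d = (xbar_sorted - mu)[:, :, None]  # (n_larvae, 3, 1)
        z = np.linalg.solve(Ls[group_of_larva], d)[:, :, 0]
        ll = -0.5 * float(np.sum(z**2)) - float(
            np.dot(group_sizes, logdet_half + 1.5 * ln2pi)
        )
        Lw = np.linalg.cholesky(cov_w)
        ll -= (n_events_total - n_larvae) * float(np.log(np.diag(Lw)).sum())
        zw = np.linalg.solve(Lw, np.linalg.solve(Lw, scatter).T)
        ll -= 0.5 * float(np.trace(zw))
        return ll

    def _scale_lp(ls: np.ndarray) -> float:
        # half-normal prior on sigma with log-transform Jacobian
        s = np.exp(ls)
        return float(np.sum(-0.5 * (s / half_normal_scale) ** 2 + ls))

    for chain in range(n_chains):
        mu = allx.mean(axis=0) + 0.1 * col_sd * rng.standard_normal(3)
        if fixed_cov is not None:
            cov_w = np.asarray(fixed_cov[0], dtype=float)
            cov_b = np.asarray(fixed_cov[1], dtype=float)
            lw = 0.5 * np.log(np.diag(cov_w))
            lb = 0.5 * np.log(np.diag(cov_b))
            rw = rb = np.zeros(3)
        else:
            lw = np.log(col_sd) + 0.2 * rng.standard_normal(3)
            lb = np.log(col_sd) + 0.2 * rng.standard_normal(3)
            rw = np.zeros(3)
            rb = np.zeros(3)
            cov_w = _cov(lw, rw)
            cov_b = _cov(lb, rb)
        # componentwise MH steps for the 6 parameters (3 log-scales, 3
        # correlations) of each covariance matrix
        step_w = np.full(6, 0.15)
        step_b = np.full(6, 0.25)

        for it in range(n_warmup + n_draws):
            # group mean | covariances (conjugate in the collapsed model)
            post_prec = prior_prec.copy()
            rhs = prior_prec @ prior_mean
            for n_i, idx in idx_by_count.items():
                Vinv = np.linalg.inv(cov_b + cov_w / n_i)
                post_prec += len(idx) * Vinv
                rhs += Vinv @ xbar[idx].sum(axis=0)
            post_cov = np.linalg.inv(post_prec)
            mu = rng.multivariate_normal(post_cov @ rhs, post_cov, method="cholesky")

            # covariance parameters (componentwise MH on the collapsed ll)
            ll = marginal_ll(mu, cov_w, cov_b) if fixed_cov is None else 0.0
            for mat, steps in () if fixed_cov is not None else (("w", step_w), ("b", step_b)):
                for j in range(6):
                    p_lw, p_rw, p_lb, p_rb = lw.copy(), rw.copy(), lb.copy(), rb.copy()
                    tgt_l, tgt_r = (p_lw, p_rw) if mat == "w" else (p_lb, p_rb)
                    if j < 3:
                        tgt_l[j] += steps[j] * rng.standard_normal()
                    else:
                        tgt_r[j - 3] += steps[j] * rng.standard_normal()
                    p_cov_w = _cov(p_lw, p_rw)
                    p_cov_b = _cov(p_lb, p_rb)
                    accepted = False
                    if p_cov_w is not None and p_cov_b is not None:
                        ll_prop = marginal_ll(mu, p_cov_w, p_cov_b)
                        dlp = _scale_lp(p_lw) + _scale_lp(p_lb) - _scale_lp(lw) - _scale_lp(lb)
                        if np.log(rng.uniform()) < ll_prop - ll + dlp:
                            lw, rw, lb, rb = p_lw, p_rw, p_lb, p_rb
                            cov_w, cov_b, ll = p_cov_w, p_cov_b, ll_prop
                            accepted = True
                    if it < n_warmup:
                        steps[j] *= float(np.exp((accepted - 0.35) / (1 + it) ** 0.6))

            if it >= n_warmup:
                j = it - n_warmup
                for k, c in enumerate(COMPONENTS):
                    keep[f"mu_{c}"][chain, j] = mu[k]
                    keep[f"sigma_b_{c}"][chain, j] = np.exp(lb[k])
                    keep[f"sigma_w_{c}"][chain, j] = np.exp(lw[k])
                if j % thin == 0:
                    # larva means | everything (conjugate), for reporting
                    m = np.empty((n_larvae, 3))
                    prec_w = np.linalg.inv(cov_w)
                    prec_b = np.linalg.inv(cov_b)
                    for n_i, idx in idx_by_count.items():
                        pp = prec_b + n_i * prec_w
                        pc = np.linalg.inv(pp)
                        L = np.linalg.cholesky(pc)
                        mean = ((prec_b @ mu)[:, None] + prec_w @ sums[idx].T).T @ pc.T
                        m[idx] = mean + rng.standard_normal((len(idx), 3)) @ L.T
                    larva_keep.append(m)

    return GroupPosterior(
        posterior=PosteriorSamples(keep),
        larva_ids=larva_ids,
        larva_mean_draws=np.asarray(larva_keep),
    )


def group_comparison(post_a: GroupPosterior, post_b: GroupPosterior) -> Dict[str, float]:
    """Componentwise P[a > b] for two groups' mean-behavior posteriors."""
    a = post_a.mu_draws()
    b = post_b.mu_draws()
    if a.shape[1] != b.shape[1]:
        raise ValueError("posteriors have mismatched component dimensions")
    return {c: prob_greater(a[:, k], b[:, k]) for k, c in enumerate(COMPONENTS)}
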