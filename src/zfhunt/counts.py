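"""Bayesian count models: hunt rates, hunt durations, capture success.

All three models share one likelihood backbone, the negative binomial
NB(r, q) with mean r (1 - q) / q, which is the marginal of a Gamma-Poisson
mixture: each larva hunts as a Poisson process with its own rate
lambda_i ~ Gamma(alpha, beta), and marginally the per-larva counts are
NB(r = alpha, q = beta / (1 + beta)).  Priors are q ~ Uniform(0, 1) and
r ~ Gamma(1, 1).  The capture model adds a conditionally conjugate
binomial-beta layer for the per-event success probability p_s.

Posteriors are sampled with an adaptive random-walk Metropolis on the
unconstrained (log r, log lambda) scale, where the posterior is close to
elliptical (three chains by default); the binomial layer is sampled
exactly from its conjugate Beta posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .samplers import (
    DEFAULT_CHAINS,
    DEFAULT_DRAWS,
    DEFAULT_WARMUP,
    PosteriorSamples,
    prob_greater,
    random_walk_metropolis,
)

__all__ = [
    "LarvaSummary",
    "fit_hunt_rate",
    "fit_hunt_duration",
    "fit_capture_model",
    "consumption_posterior",
    "efficiency_and_hpi",
    "prob_greater",
    "nb_log_likelihood",
]


@dataclass
class LarvaSummary:
    """Per-larva counts for one 10-minute recording pair."""

    larva_id: str
    group: str = ""
    spont_count: int = 0
    evoked_count: int = 0
    hunt_frames: int = 0
    attempts: int = 0
    successes: int = 0
    fps: float = 410.0

    def __post_init__(self) -> None:
        for name in ("spont_count", "evoked_count", "hunt_frames", "attempts", "successes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.successes > self.attempts:
            raise ValueError("successes cannot exceed attempts")


def nb_log_likelihood(counts: np.ndarray, r, q) -> np.ndarray:
    """Sum of NB(r, q) log-pmfs over counts, vectorized over (r, q) arrays.

    Parametrization: P(h) = C(h + r - 1, h) q^r (1-q)^h, mean r(1-q)/q.
    """
    counts = np.asarray(counts, dtype=float)
    r = np.asarray(r, dtype=float)[..., None]
    q = np.asarray(q, dtype=float)[..., None]
    ll = (
        gammaln(counts + r)
        - gammaln(r)
        - gammaln(counts + 1.0)
        + r * np.log(q)
        + counts * np.log1p(-q)
    )
    return ll.sum(axis=-1)


def _fit_nb(
    counts: np.ndarray,
    *,
    n_chains: int,
    n_draws: int,
    n_warmup: int,
    rng: np.random.Generator,
) -> PosteriorSamples:
    """NB(r, q) posterior with priors r ~ Gamma(1,1), q ~ Uniform(0,1)."""
    counts = np.asarray(counts)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("need counts for at least two larvae")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")

    # sample on (log r, log lam): the NB posterior is close to elliptical and
    # weakly correlated in this parametrization, unlike (r, q)
    def log_post(x: np.ndarray) -> np.ndarray:
        r = np.exp(x[:, 0])
        lam = np.exp(x[:, 1])
        q = r / (r + lam)
        ll = nb_log_likelihood(counts, r, q)
        # priors r ~ Gamma(1,1), q ~ U(0,1), with the Jacobian of
        # (r, q) -> (log r, log lam): r * lam * r / (r + lam)^2
        lp = -r + 2 * x[:, 0] + x[:, 1] - 2 * np.log(r + lam)
        out = ll + lp
        return np.where(np.isfinite(out), out, -np.inf)

    mean0 = max(counts.mean(), 0.1)
    x0 = np.column_stack(
        [
            0.5 * rng.standard_normal(n_chains),
            np.log(mean0) + 0.3 * rng.standard_normal(n_chains),
        ]
    )
    draws = random_walk_metropolis(
        log_post, x0, n_draws=n_draws, n_warmup=n_warmup, rng=rng
    )
    r = np.exp(draws[:, :, 0])
    lam = np.exp(draws[:, :, 1])
    q = r / (r + lam)
    return PosteriorSamples({"r": r, "q": q, "lam": lam})


def fit_hunt_rate(
    counts: Sequence[int],
    *,
    n_chains: int = DEFAULT_CHAINS,
    n_draws: int = DEFAULT_DRAWS,
    n_warmup: int = DEFAULT_WARMUP,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Posterior over (r, q, lam) for per-larva hunt-event counts.

    ``lam = r (1 - q) / q`` is the group mean hunt rate (events/10 min); the
    Gamma mixing distribution is recovered as shape alpha = r and rate
    beta = q / (1 - q).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    return _fit_nb(
        np.asarray(counts, dtype=int),
        n_chains=n_chains,
        n_draws=n_draws,
        n_warmup=n_warmup,
        rng=rng,
    )


def fit_hunt_duration(
    hunt_frames: Sequence[int],
    fps: float = 410.0,
    *,
    n_chains: int = DEFAULT_CHAINS,
    n_draws: int = DEFAULT_DRAWS,
    n_warmup: int = DEFAULT_WARMUP,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Posterior over (r, q, mu_seconds) for per-larva total hunt frames.

    The same NB machinery on frame counts; mu_seconds converts the NB mean
    from frames to seconds at the given frame rate.  Larvae with zero hunt
    events (zero frames) must be excluded by the caller: a detected event
    lasts at least 100 frames, so zeros make the distribution discontinuous.
    """
    frames = np.asarray(hunt_frames, dtype=int)
    if np.any(frames == 0):
        raise ValueError(
            "larvae with zero hunt frames must be excluded before fitting "
            "(exclusion rule for the duration model)"
        )
    rng = rng if rng is not None else np.random.default_rng(seed)
    post = _fit_nb(frames, n_chains=n_chains, n_draws=n_draws, n_warmup=n_warmup, rng=rng)
    mu_seconds = post.draws["lam"] / fps
    return PosteriorSamples({**post.draws, "mu_seconds": mu_seconds})


def fit_capture_model(
    attempts: Sequence[int],
    successes: Sequence[int],
    *,
    n_chains: int = DEFAULT_CHAINS,
    n_draws: int = DEFAULT_DRAWS,
    n_warmup: int = DEFAULT_WARMUP,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Joint posterior over attempt-rate parameters and success probability.

    Attempts h ~ NB(r, q); successes Ns ~ Binomial(h, p_s) with a flat
    Beta(1, 1) prior on p_s.  Given the observed attempts, p_s is
    conditionally conjugate and is drawn exactly from
    Beta(1 + sum Ns, 1 + sum (h - Ns)).  mu_C = r (1 - q) / q is the mean
    number of capture attempts per recording.
    """
    h = np.asarray(attempts, dtype=int)
    ns = np.asarray(successes, dtype=int)
    if h.shape != ns.shape:
        raise ValueError("attempts and successes must align")
    if np.any(ns > h):
        raise ValueError("successes cannot exceed attempts")
    if np.any(h == 0):
        raise ValueError("larvae with zero attempts must be excluded before fitting")
    rng = rng if rng is not None else np.random.default_rng(seed)
    post = _fit_nb(h, n_chains=n_chains, n_draws=n_draws, n_warmup=n_warmup, rng=rng)
    a = 1.0 + ns.sum()
    b = 1.0 + (h - ns).sum()
    p_s = rng.beta(a, b, size=post.draws["r"].shape)
    return PosteriorSamples(
        {"r": post.draws["r"], "q": post.draws["q"], "mu_C": post.draws["lam"], "p_s": p_s}
    )


def consumption_posterior(fit: PosteriorSamples) -> np.ndarray:
    """Per-draw consumption rate: mu_C x p_s (prey per 10 min), flattened."""
    if "mu_C" not in fit.draws or "p_s" not in fit.draws:
        raise ValueError("fit must contain mu_C and p_s draws")
    return fit.get("mu_C") * fit.get("p_s")


def efficiency_and_hpi(summaries: Sequence[LarvaSummary]) -> pd.DataFrame:
    """Per-larva capture efficiency and hunt power index.

    efficiency = successes / attempts; HPI = efficiency x successes.  Larvae
    without any capture attempt are excluded (with a log notice) because
    efficiency is undefined for them.
    """
    import logging

    rows = []
    for s in summaries:
        if s.attempts == 0:
            logging.getLogger(__name__).info(
                "excluding larva %s: no capture attempts", s.larva_id
            )
            continue
        eff = s.successes / s.attempts
        rows.append(
            {
                "larva_id": s.larva_id,
                "group": s.group,
                "attempts": s.attempts,
                "successes": s.successes,
                "efficiency": eff,
                "hpi": eff * s.successes,
            }
        )
    return pd.DataFrame(rows)


def nb_posterior_grid(
    counts: Sequence[int], n_grid: int = 400
) -> tuple[float, float, float]:
    """Brute-force posterior means of (r, q, lam) by 2-D grid quadrature.

    Independent oracle for the Metropolis sampler: evaluates the NB
    posterior with priors r ~ Gamma(1,1), q ~ U(0,1) on a fine (r, q) grid
    and integrates numerically.  Only feasible for small problems.
    """
    counts = np.asarray(counts, dtype=int)
    mean = counts.mean() + 1.0
    r_grid = np.linspace(1e-3, 30.0, n_grid)
    q_grid = np.linspace(1e-4, 1 - 1e-4, n_grid)
    R, Q = np.meshgrid(r_grid, q_grid, indexing="ij")
    ll = nb_log_likelihood(counts, R.ravel(), Q.ravel()).reshape(R.shape)
    log_post = ll - R  # Gamma(1,1) prior on r; flat on q
    log_post -= log_post.max()
    w = np.exp(log_post)
    z = w.sum()
    lam = R * (1 - Q) / Q
    return (
        float((w * R).sum() / z),
        float((w * Q).sum() / z),
        float((w * lam).sum() / z),
    )
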