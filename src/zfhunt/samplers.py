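"""MCMC building blocks shared by every model in the package.

No probabilistic-programming framework is assumed: each model in
:mod:`zfhunt` implements its own Gibbs or adaptive-Metropolis scheme on
top of the helpers here, and the conjugate / quadrature / enumeration
oracles in the test suite guard the implementations.

Draws are stored per chain so that split-R-hat and effective sample size
(computed with :mod:`arviz`) are always available for every reported
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict

import arviz as az
import numpy as np
import pandas as pd

__all__ = [
    "PosteriorSamples",
    "prob_greater",
    "random_walk_metropolis",
    "check_convergence",
]

# Default MCMC contract: 3 chains, 2000 retained draws each, R-hat < 1.05.
DEFAULT_CHAINS = 3
DEFAULT_DRAWS = 2000
DEFAULT_WARMUP = 1000
RHAT_THRESHOLD = 1.05


@dataclass
class PosteriorSamples:
    """Named MCMC draws for one fitted model, with convergence metadata.

    Parameters are stored as ``(n_chains, n_draws)`` arrays.  Vector-valued
    quantities that are not convergence-monitored (e.g. per-larva means)
    live in :attr:`extra`.
    """

    draws: Dict[str, np.ndarray]
    extra: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.draws.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent draw shapes: {shapes}")
        for name, arr in self.draws.items():
            if arr.ndim != 2:
                raise ValueError(f"{name}: draws must be (n_chains, n_draws)")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def names(self) -> list[str]:
        return list(self.draws)

    def get(self, name: str) -> np.ndarray:
        """Flattened draws (all chains concatenated) for one parameter."""
        return np.asarray(self.draws[name]).reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.get(name).mean())

    def ci(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        """Central credible interval (equal-tailed)."""
        lo, hi = np.quantile(self.get(name), [(1 - prob) / 2, (1 + prob) / 2])
        return float(lo), float(hi)

    def _dataset(self):
        return az.convert_to_dataset({k: v for k, v in self.draws.items()})

    def rhat(self) -> Dict[str, float]:
        ds = az.rhat(self._dataset())
        return {k: float(ds[k].values) for k in self.draws}

    def ess(self) -> Dict[str, float]:
        ds = az.ess(self._dataset())
        return {k: float(ds[k].values) for k in self.draws}

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        rhat = self.rhat()
        ess = self.ess()
        rows = []
        for name in self.draws:
            lo, hi = self.ci(name, prob)
            rows.append(
                {
                    "parameter": name,
                    "mean": self.mean(name),
                    "sd": float(self.get(name).std(ddof=1)),
                    f"ci{prob:.0%}_lo": lo,
                    f"ci{prob:.0%}_hi": hi,
                    "rhat": rhat[name],
                    "ess": ess[name],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def to_frame(self) -> pd.DataFrame:
        """One column of flattened draws per parameter."""
        return pd.DataFrame({k: self.get(k) for k in self.draws})


def check_convergence(post: PosteriorSamples, threshold: float = RHAT_THRESHOLD) -> Dict[str, float]:
    """Return the R-hat table; warn (do not fail) on parameters above threshold."""
    rhat = post.rhat()
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > threshold}
    if bad:
        import warnings

        warnings.warn(f"R-hat above {threshold}: {bad}", RuntimeWarning, stacklevel=2)
    return rhat


def prob_greater(a_draws: np.ndarray, b_draws: np.ndarray) -> float:
    """Posterior probability P[a > b] from paired MCMC draws.

    The fraction of paired draws where ``a_i > b_i``; ties count one half.
    Unequal-length inputs are cycled (deterministically) to a common length.
    """
    a = np.asarray(a_draws, dtype=float).reshape(-1)
    b = np.asarray(b_draws, dtype=float).reshape(-1)
    if a.size == 0 or b.size == 0:
        raise ValueError("prob_greater requires non-empty draw vectors")
    n = max(a.size, b.size)
    if a.size != b.size:
        a = np.resize(a, n)
        b = np.resize(b, n)
    return float(np.mean((a > b) + 0.5 * (a == b)))


def random_walk_metropolis(
    log_post: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    *,
    n_draws: int = DEFAULT_DRAWS,
    n_warmup: int = DEFAULT_WARMUP,
    rng: np.random.Generator,
    step0: float = 0.25,
    target_accept: float = 0.3,
) -> np.ndarray:
    """Adaptive Gaussian random-walk Metropolis, vectorized over chains.

    ``log_post`` maps an ``(n_chains, dim)`` array of unconstrained states to
    ``(n_chains,)`` log posterior densities.  Per-chain scalar step sizes are
    adapted toward ``target_accept`` during warm-up only (diminishing
    adaptation), then frozen.

    Returns draws of shape ``(n_chains, n_draws, dim)``.
    """
    x = np.array(x0, dtype=float)
    if x.ndim != 2:
        raise ValueError("x0 must be (n_chains, dim)")
    n_chains, dim = x.shape
    lp = log_post(x)
    step = np.full(n_chains, step0)
    out = np.empty((n_chains, n_draws, dim))
    total = n_warmup + n_draws
    for it in range(total):
        prop = x + step[:, None] * rng.standard_normal((n_chains, dim))
        lp_prop = log_post(prop)
        accept = np.log(rng.uniform(size=n_chains)) < (lp_prop - lp)
        x[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        if it < n_warmup:
            # Robbins-Monro step-size adaptation
            gamma = 1.0 / (1 + it) ** 0.6
            step *= np.exp(gamma * (accept.astype(float) - target_accept))
        else:
            out[:, it - n_warmup, :] = x
    return out
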