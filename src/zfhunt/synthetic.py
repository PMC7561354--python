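"""Synthetic behavioral data with known ground truth.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the downstream models assume: Gamma-mixed Poisson
hunt counts (marginally negative binomial), NB-distributed capture
attempts with binomial successes, linear turn responses to bimodally
placed prey azimuths, a two-component correlated bivariate Gaussian
mixture over (capture speed, prey distance), a two-level multivariate
normal hierarchy of per-larva mean behavior, and eye-vergence tracking
traces with embedded hunt events for exercising the detector.

The shipped default configurations mirror the printed LF / NF / DF group
summaries (evoked hunt rates 13.3 / 11.9 / 12.1 events per 10 min,
success probabilities 0.32 / 0.21 / 0.18, turn slopes 0.73 / 0.87 / 0.92,
fast-capture fractions 0.41 / 0.28 / 0.21, group mean behavior vectors
(28.2 mm/s, 0.35 mm, 0.85) etc.) so end-to-end runs are directly
comparable with the study-scale figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MixtureTruth",
    "GroupConfig",
    "default_configs",
    "load_configs",
    "dump_configs",
    "simulate_counts",
    "simulate_hunt_frames",
    "simulate_capture_outcomes",
    "simulate_turn_pairs",
    "simulate_capture_points",
    "simulate_group_hierarchy",
    "CaptureKinematics",
    "simulate_trace",
]

RECORDING_MINUTES = 10.0  # all count rates are per 10-minute recording
DEFAULT_FPS = 410.0


def _rng_for(cfg: "GroupConfig", rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


@dataclass(frozen=True)
class MixtureTruth:
    """Ground truth for the two-component (speed, distance) Gaussian mixture.

    Units: speed mm/s, distance mm.  The fast cluster must have the larger
    mean speed — that ordering is what identifies the clusters downstream.
    """

    slow_mean: Tuple[float, float] = (5.0, 0.15)
    fast_mean: Tuple[float, float] = (35.0, 0.45)
    slow_sd: Tuple[float, float] = (1.5, 0.08)
    fast_sd: Tuple[float, float] = (8.0, 0.15)
    rho_slow: float = 0.0
    rho_fast: float = 0.6

    def __post_init__(self) -> None:
        if not self.fast_mean[0] > self.slow_mean[0]:
            raise ValueError("fast cluster must have larger mean speed than slow")
        for sd in (*self.slow_sd, *self.fast_sd):
            if sd <= 0:
                raise ValueError("cluster standard deviations must be positive")
        for rho in (self.rho_slow, self.rho_fast):
            if not -1 < rho < 1:
                raise ValueError("correlations must lie strictly in (-1, 1)")

    def mean(self, cluster: str) -> np.ndarray:
        return np.asarray(self.slow_mean if cluster == "slow" else self.fast_mean)

    def cov(self, cluster: str) -> np.ndarray:
        if cluster == "slow":
            ss, sd = self.slow_sd
            rho = self.rho_slow
        else:
            ss, sd = self.fast_sd
            rho = self.rho_fast
        return np.array([[ss**2, rho * ss * sd], [rho * ss * sd, sd**2]])


@dataclass
class GroupConfig:
    """Generating parameters for one rearing group (LF, NF or DF).

    Count parameters follow the NB(r, q) parametrization with mean
    ``r (1 - q) / q``; the Gamma mixing of Poisson rates is recovered as
    shape ``alpha = r`` and rate ``beta = q / (1 - q)``.
    """

    group_label: str
    n_larvae: int = 60
    # Gamma mixing of Poisson hunt rates, (shape alpha, rate beta), events/10 min
    rate_evoked: Tuple[float, float] = (3.0, 3.0 / 13.3)
    rate_spont: Tuple[float, float] = (3.0, 3.0 / 3.6)
    # NB (r, q) on total hunt frames per recording
    duration_nb: Tuple[float, float] = (3.0, 3.0 / (3.0 + 35.5 * DEFAULT_FPS))
    # NB (r, q) on capture attempts per recording
    attempt_nb: Tuple[float, float] = (3.0, 3.0 / (3.0 + 10.9))
    p_success: float = 0.32
    turn_slope: float = 0.73
    turn_intercept: float = 0.0
    turn_noise_sd: float = 10.0
    mixture: MixtureTruth = field(default_factory=MixtureTruth)
    p_fast: float = 0.41
    azimuth_modes: Tuple[float, float] = (35.0, 50.0)
    # group mean (capture speed mm/s, capture distance mm, turn-ratio) for the
    # two-level hierarchy of per-larva mean behavior
    hier_mean: Tuple[float, float, float] = (28.2, 0.35, 0.85)
    n_success_events: int = 92
    fps: float = DEFAULT_FPS
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.mixture, dict):
            self.mixture = MixtureTruth(
                **{
                    k: tuple(v) if isinstance(v, (list, tuple)) else v
                    for k, v in self.mixture.items()
                }
            )
        for p in (self.p_success, self.p_fast):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for name in ("rate_evoked", "rate_spont", "duration_nb", "attempt_nb"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name}: parameters must be strictly positive")
        if not (self.duration_nb[1] <= 1 and self.attempt_nb[1] <= 1):
            raise ValueError("NB probability parameter q must lie in (0, 1]")
        lo, hi = self.azimuth_modes
        if not 0 < lo < hi:
            raise ValueError("azimuth modes must satisfy 0 < lo < hi")
        if self.n_larvae < 1:
            raise ValueError("n_larvae must be >= 1")
        if self.turn_noise_sd < 0:
            raise ValueError("turn_noise_sd must be >= 0")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroupConfig":
        d = dict(d)
        if "mixture" in d and isinstance(d["mixture"], dict):
            mix = {k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in d["mixture"].items()}
            d["mixture"] = MixtureTruth(**mix)
        for key in ("rate_evoked", "rate_spont", "duration_nb", "attempt_nb",
                    "azimuth_modes", "hier_mean"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def nb_mean(r: float, q: float) -> float:
    """Mean of NB(r, q): r (1 - q) / q."""
    return r * (1.0 - q) / q


def nb_rq_from_mean(mean: float, r: float = 3.0) -> Tuple[float, float]:
    """(r, q) of a negative binomial with the given mean and size r."""
    return r, r / (r + mean)


def default_configs() -> Dict[str, GroupConfig]:
    """LF / NF / DF configurations mirroring the printed group summaries."""
    fps = DEFAULT_FPS
    return {
        "LF": GroupConfig(
            group_label="LF",
            rate_evoked=(3.0, 3.0 / 13.3),
            rate_spont=(3.0, 3.0 / 3.6),
            duration_nb=nb_rq_from_mean(35.5 * fps),
            attempt_nb=nb_rq_from_mean(10.9),
            p_success=0.32,
            turn_slope=0.73,
            p_fast=0.41,
            hier_mean=(28.2, 0.35, 0.85),
            n_success_events=92,
            seed=1,
        ),
        "NF": GroupConfig(
            group_label="NF",
            rate_evoked=(3.0, 3.0 / 11.9),
            rate_spont=(3.0, 3.0 / 3.8),
            duration_nb=nb_rq_from_mean(47.0 * fps),
            attempt_nb=nb_rq_from_mean(9.2),
            p_success=0.21,
            turn_slope=0.87,
            p_fast=0.28,
            hier_mean=(17.5, 0.23, 0.94),
            n_success_events=69,
            seed=2,
        ),
        "DF": GroupConfig(
            group_label="DF",
            rate_evoked=(3.0, 3.0 / 12.1),
            rate_spont=(3.0, 3.0 / 3.5),
            duration_nb=nb_rq_from_mean(42.5 * fps),
            attempt_nb=nb_rq_from_mean(8.9),
            p_success=0.18,
            turn_slope=0.92,
            p_fast=0.21,
            hier_mean=(23.3, 0.24, 0.92),
            n_success_events=45,
            seed=3,
        ),
    }


def load_configs(path) -> Dict[str, GroupConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: GroupConfig.from_dict(v) for k, v in raw.items()}


def dump_configs(configs: Dict[str, GroupConfig], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: v.to_dict() for k, v in configs.items()}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# count generators
# ---------------------------------------------------------------------------

def simulate_counts(
    cfg: GroupConfig,
    condition: str = "evoked",
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Per-larva hunt-event counts from the Gamma-Poisson mixture.

    Each larva draws its own rate ``lambda_i ~ Gamma(alpha, beta)`` and then a
    count ``~ Poisson(lambda_i)``; marginally the counts are negative binomial
    NB(r=alpha, q=beta/(1+beta)), which is the between-larva overdispersion
    the count models assume.
    """
    if condition not in ("evoked", "spontaneous"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = _rng_for(cfg, rng)
    alpha, beta = cfg.rate_evoked if condition == "evoked" else cfg.rate_spont
    lam = rng.gamma(alpha, 1.0 / beta, size=cfg.n_larvae)
    return rng.poisson(lam)


def simulate_hunt_frames(cfg: GroupConfig, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Per-larva total hunt-frame counts, NB(duration_nb)."""
    rng = _rng_for(cfg, rng)
    r, q = cfg.duration_nb
    return rng.negative_binomial(r, q, size=cfg.n_larvae)


def simulate_capture_outcomes(
    cfg: GroupConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Per-larva capture attempts h ~ NB and successes Ns ~ Binomial(h, p).

    Returns a DataFrame with columns larva_id, attempts, successes; the
    invariant ``successes <= attempts`` holds by construction.
    """
    rng = _rng_for(cfg, rng)
    r, q = cfg.attempt_nb
    h = rng.negative_binomial(r, q, size=cfg.n_larvae)
    ns = rng.binomial(h, cfg.p_success)
    return pd.DataFrame(
        {
            "larva_id": [f"{cfg.group_label}_{i:03d}" for i in range(cfg.n_larvae)],
            "attempts": h,
            "successes": ns,
        }
    )


def sample_azimuths(
    modes: Tuple[float, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric bimodal prey azimuths: uniform over +/-[lo, hi] degrees."""
    lo, hi = modes
    side = rng.choice([-1.0, 1.0], size=n)
    return side * rng.uniform(lo, hi, size=n)


def simulate_turn_pairs(
    cfg: GroupConfig, n_events: int, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """(prey azimuth theta, first-turn phi) pairs from the linear turn model.

    theta is drawn from the bimodal placement over ±[lo, hi]; the response is
    ``phi = beta0 + beta1 * theta + Normal(0, turn_noise_sd)``.  Both angles
    share the same sign convention, so expected phi has theta's sign.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = _rng_for(cfg, rng)
    theta = sample_azimuths(cfg.azimuth_modes, n_events, rng)
    phi = (
        cfg.turn_intercept
        + cfg.turn_slope * theta
        + cfg.turn_noise_sd * rng.standard_normal(n_events)
    )
    return pd.DataFrame({"theta_deg": theta, "phi_deg": phi})


def simulate_capture_points(
    cfg: GroupConfig, n_events: int, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """(capture speed, prey distance) draws from the two-cluster mixture.

    Cluster labels are Bernoulli(p_fast) and retained in the output (column
    ``true_label``: 'fast'/'slow') for recovery tests.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = _rng_for(cfg, rng)
    fast = rng.uniform(size=n_events) < cfg.p_fast
    pts = np.empty((n_events, 2))
    for cluster, mask in (("slow", ~fast), ("fast", fast)):
        k = int(mask.sum())
        if k:
            pts[mask] = rng.multivariate_normal(
                cfg.mixture.mean(cluster), cfg.mixture.cov(cluster), size=k
            )
    # speeds/distances are physical quantities; clip stray negatives from the
    # Gaussian tails to zero
    pts = np.clip(pts, 0.0, None)
    return pd.DataFrame(
        {
            "capture_speed_mm_s": pts[:, 0],
            "capture_distance_mm": pts[:, 1],
            "true_label": np.where(fast, "fast", "slow"),
        }
    )


def _check_psd(name: str, cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
        raise ValueError(f"{name} must be a symmetric 3x3 matrix")
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-10:
        raise ValueError(f"{name} must be positive semi-definite")
    return cov


def simulate_group_hierarchy(
    cfg: GroupConfig,
    between_cov: np.ndarray,
    within_cov: np.ndarray,
    events_per_larva: Sequence[int],
    rng: Optional[np.random.Generator] = None,
    group_mean: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Two-level hierarchy of per-event (speed, distance, turn-ratio).

    Larva mean vectors are MVN(group mean, between_cov); events are
    MVN(larva mean, within_cov).  The group mean defaults to the config's
    ``hier_mean`` vector.  Returns one row per event, tagged by larva.
    """
    between_cov = _check_psd("between_cov", between_cov)
    within_cov = _check_psd("within_cov", within_cov)
    events_per_larva = np.asarray(events_per_larva, dtype=int)
    if events_per_larva.min() < 1:
        raise ValueError("every larva needs at least one event")
    rng = _rng_for(cfg, rng)
    mu = np.asarray(group_mean if group_mean is not None else cfg.hier_mean, dtype=float)
    n_larvae = len(events_per_larva)
    larva_means = rng.multivariate_normal(mu, between_cov, size=n_larvae, method="svd")
    rows = []
    for i, (m, k) in enumerate(zip(larva_means, events_per_larva)):
        ev = rng.multivariate_normal(m, within_cov, size=int(k), method="svd")
        for e in ev:
            rows.append((f"{cfg.group_label}_{i:03d}", *e))
    df = pd.DataFrame(
        rows, columns=["larva_id", "capture_speed_mm_s", "capture_distance_mm", "turn_ratio"]
    )
    df.attrs["larva_means"] = larva_means
    return df


# ---------------------------------------------------------------------------
# tracking-trace generator (fixture for the event detector)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaptureKinematics:
    """Per-event kinematics embedded in a simulated trace.

    When attached to :func:`simulate_trace`, each vergence episode also
    contains a stationary prey target, a first turn of magnitude
    ``turn_ratio * azimuth`` and a final lunge peaking at ``capture_speed``
    launched from ``capture_distance`` (mouth tip to prey).
    """

    azimuth_deg: float = 40.0
    turn_ratio: float = 0.73
    capture_speed: float = 28.2  # mm/s
    capture_distance: float = 0.35  # mm
    mouth_offset_mm: float = 0.5


def _unit(deg: float) -> np.ndarray:
    r = math.radians(deg)
    return np.array([math.cos(r), math.sin(r)])


def _raised_cosine(n: int) -> np.ndarray:
    """Smooth speed pulse of n samples, peak 1, zero at both ends."""
    t = np.arange(n) / max(n - 1, 1)
    return 0.5 * (1 - np.cos(2 * np.pi * t))


def _splice_motion(head: np.ndarray, start: int, new_pos: np.ndarray) -> None:
    """Overwrite head[start:start+len(new_pos)] and shift the remainder so the
    trajectory stays continuous (relative increments preserved)."""
    end = start + len(new_pos)
    tail = head[end:].copy()
    head[start:end] = new_pos
    if len(tail):
        head[end:] = tail - tail[0] + new_pos[-1]


def simulate_trace(
    events: Iterable[Tuple[float, float]],
    recording_s: float,
    fps: float = DEFAULT_FPS,
    rng: Optional[np.random.Generator] = None,
    *,
    seed: int = 0,
    baseline_eye_deg: float = 10.0,
    plateau_eye_deg: float = 30.0,
    jitter_sd_deg: float = 2.0,
    kinematics: Optional[CaptureKinematics] = None,
):
    """Synthetic tracking trace with constructed hunt events.

    ``events`` is a list of (start_s, duration_s) episodes, non-overlapping
    and inside the recording window.  Outside events the eyes rest at a
    vergence of ``2 * baseline_eye_deg`` (below the 45-degree detection
    threshold); during events they ramp to ``2 * plateau_eye_deg`` with each
    eye ``plateau_eye_deg`` inward (comfortably beyond the 45/19-degree
    rule), with additive Gaussian jitter well below half the margin.  The
    head follows a slow random walk whose speed stays below the 4 mm/s bout
    threshold.

    With ``kinematics`` set, each event (which must then last at least
    0.6 s) additionally embeds a prey target, a first-turn bout and a
    capture lunge so the full feature-extraction path can run.  Event
    azimuth sign alternates between events.

    Returns a :class:`zfhunt.kinematics.TrackingTrace`.
    """
    from .kinematics import TrackingTrace  # local import: avoid cycle

    rng = rng if rng is not None else np.random.default_rng(seed)
    events = sorted((float(s), float(d)) for s, d in events)
    for (s, d) in events:
        if d <= 0 or s < 0 or s + d > recording_s:
            raise ValueError("events must lie inside the recording window")
    for (s1, d1), (s2, _) in zip(events, events[1:]):
        if s1 + d1 > s2:
            raise ValueError("events must not overlap")
    if kinematics is not None and any(d < 0.6 for _, d in events):
        raise ValueError("kinematic events must last at least 0.6 s")

    n = int(round(recording_s * fps))
    t = np.arange(n) / fps
    left = np.full(n, baseline_eye_deg)
    right = np.full(n, -baseline_eye_deg)
    heading = np.zeros(n)
    # slow random walk: per-frame steps far below the 4 mm/s bout threshold
    step_sd = 0.4 / fps  # ~0.4 mm/s drift speed
    head = np.cumsum(step_sd * rng.standard_normal((n, 2)), axis=0)
    prey = np.full((n, 2), np.nan)

    ramp = max(4, int(round(0.02 * fps)))
    cur_heading = 0.0
    for k, (start_s, dur_s) in enumerate(events):
        i0 = int(round(start_s * fps))
        i1 = min(int(round((start_s + dur_s) * fps)), n)
        # eye plateau with entry/exit ramps inside the episode
        up = np.linspace(0, 1, ramp)
        seg = np.ones(i1 - i0)
        seg[:ramp] = up
        seg[-ramp:] = up[::-1]
        delta = plateau_eye_deg - baseline_eye_deg
        left[i0:i1] += delta * seg
        right[i0:i1] -= delta * seg

        if kinematics is None:
            continue

        kin = kinematics
        theta = kin.azimuth_deg * (1 if k % 2 == 0 else -1)
        phi = kin.turn_ratio * theta
        h0 = cur_heading
        h1 = h0 + phi
        p0 = head[i0].copy()
        u_bear = _unit(h0 + theta)  # prey bearing, measured from the mouth tip
        mouth0 = p0 + kin.mouth_offset_mm * _unit(h0)

        # turn bout: raised-cosine speed pulse peaking at 12 mm/s, advancing
        # along the prey bearing; the heading ramp is confined to the
        # super-threshold core of the pulse so the net change over the
        # detected bout equals phi
        turn_peak = 12.0
        tb0 = i0 + int(round(0.05 * fps))
        tb_n = int(round(0.12 * fps))
        pulse = _raised_cosine(tb_n)
        adv = turn_peak * np.sum(pulse) / fps  # total turn-bout displacement

        # geometry: at capture-bout onset the mouth tip must sit exactly
        # capture_distance from the prey
        th, ph = math.radians(theta), math.radians(phi)
        along = 0.5 * (math.cos(th) - math.cos(th - ph)) * kin.mouth_offset_mm / 0.5
        perp = kin.mouth_offset_mm * (math.sin(th - ph) - math.sin(th))
        if kin.capture_distance <= abs(perp):
            raise ValueError("capture_distance too small for the mouth-offset geometry")
        reach = adv - along + math.sqrt(kin.capture_distance**2 - perp**2)
        prey_pos = mouth0 + reach * u_bear

        core = pulse >= 5.0 / turn_peak  # frames safely above the 4 mm/s threshold
        frac = np.zeros(tb_n)
        frac[core] = np.cumsum(pulse[core]) / pulse[core].sum()
        frac[np.cumsum(core) == core.sum()] = 1.0
        heading[tb0 : tb0 + tb_n] = h0 + phi * frac
        heading[tb0 + tb_n :] = h1
        disp = np.cumsum(pulse) * turn_peak / fps
        pos = head[tb0 - 1] + disp[:, None] * u_bear
        _splice_motion(head, tb0, pos)

        # capture bout: raised-cosine lunge along mouth->prey, overshooting
        # the prey position so a closest-approach frame exists
        cb0 = i0 + int(round(0.35 * fps))
        mouth = head[cb0 - 1] + kin.mouth_offset_mm * _unit(h1)
        v = prey_pos - mouth
        v = v / np.linalg.norm(v)
        lunge_len = float(np.linalg.norm(prey_pos - head[cb0 - 1])) + 0.3
        cb_dur = 2.0 * lunge_len / kin.capture_speed
        cb_n = max(8, int(round(cb_dur * fps)))
        if cb0 + cb_n > i1 - ramp:
            raise ValueError("event too short for the embedded capture bout")
        pulse = _raised_cosine(cb_n)
        # per-frame speed peaks at capture_speed; displacement is its integral
        disp = np.cumsum(pulse * kin.capture_speed / fps)
        disp *= lunge_len / disp[-1]
        _splice_motion(head, cb0, head[cb0 - 1] + disp[:, None] * v)
        prey[i0:i1] = prey_pos
        cur_heading = h1

    left = left + jitter_sd_deg * rng.standard_normal(n)
    right = right + jitter_sd_deg * rng.standard_normal(n)

    return TrackingTrace(
        frame=np.arange(n),
        time_s=t,
        left_eye_deg=left,
        right_eye_deg=right,
        head_x_mm=head[:, 0],
        head_y_mm=head[:, 1],
        heading_deg=heading,
        prey_x_mm=prey[:, 0],
        prey_y_mm=prey[:, 1],
        fps=fps,
    )
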