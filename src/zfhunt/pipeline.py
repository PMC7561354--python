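"""Reproducible simulate -> detect -> fit -> report orchestration.

A run is described by a single :class:`RunConfig` (YAML round-trippable)
that collects every fixed constant of the analysis — detection thresholds,
MCMC settings, membership threshold, minimum attempts — so no stage hides
a default.  Stages form a fixed DAG; each writes its outputs under the run
directory and records status in a manifest (config hash, seeds, package
versions, per-stage status).  Reruns with an unchanged config hash skip
completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import counts as counts_mod
from . import groups as groups_mod
from . import mixture as mixture_mod
from . import turning as turning_mod
from .behavior_space import build_behavior_matrix, pca_embed, pcr_efficiency
from .samplers import prob_greater
from .synthetic import (
    GroupConfig,
    default_configs,
    simulate_capture_outcomes,
    simulate_capture_points,
    simulate_counts,
    simulate_group_hierarchy,
    simulate_hunt_frames,
    simulate_turn_pairs,
)

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = [
    "simulate",
    "fit_rates",
    "fit_duration",
    "fit_capture",
    "fit_turn",
    "fit_mixture",
    "fit_group",
    "pca",
    "report",
]


@dataclass
class Thresholds:
    """Fixed analysis constants (defaults are the printed values)."""

    vergence_deg: float = 45.0
    eye_inward_deg: float = 19.0
    min_event_frames: int = 100
    merge_gap_frames: int = 300
    speed_threshold_mm_s: float = 4.0
    membership: float = 0.7
    min_attempts: int = 5


@dataclass
class MCMCSettings:
    chains: int = 3
    draws: int = 2000
    warmup: int = 1000
    seed: int = 1


@dataclass
class RunConfig:
    out_dir: str = "zfhunt_run"
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))
    groups: Optional[Dict[str, dict]] = None  # None -> shipped default configs
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    thresholds: Thresholds = field(default_factory=Thresholds)
    hierarchy_larvae: int = 40
    pcr_components: int = 2

    def group_configs(self) -> Dict[str, GroupConfig]:
        if self.groups is None:
            return default_configs()
        return {k: GroupConfig.from_dict(v) for k, v in self.groups.items()}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("mcmc"), dict):
            d["mcmc"] = MCMCSettings(**d["mcmc"])
        if isinstance(d.get("thresholds"), dict):
            d["thresholds"] = Thresholds(**d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _summary_json(post, names, path: Path) -> dict:
    out = {}
    rhat = post.rhat()
    for name in names:
        lo, hi = post.ci(name)
        out[name] = {
            "mean": post.mean(name),
            "ci95": [lo, hi],
            "rhat": rhat[name],
        }
    path.write_text(json.dumps(out, indent=2))
    return out


class _Run:
    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
            if self.manifest.get("config_hash") != config.hash():
                self.manifest = self._fresh_manifest()
        else:
            self.manifest = self._fresh_manifest()
        self.posteriors: Dict[str, dict] = {}

    def _fresh_manifest(self) -> dict:
        import zfhunt

        return {
            "config_hash": self.cfg.hash(),
            "seed": self.cfg.mcmc.seed,
            "versions": {
                "zfhunt": getattr(zfhunt, "__version__", "0"),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "stages": {},
        }

    def rng(self, tag: str) -> np.random.Generator:
        h = int(hashlib.sha256(f"{self.cfg.mcmc.seed}:{tag}".encode()).hexdigest()[:8], 16)
        return np.random.default_rng(h)

    def done(self, stage: str) -> bool:
        return self.manifest["stages"].get(stage, {}).get("status") == "done"

    def mark(self, stage: str, status: str, **info) -> None:
        self.manifest["stages"][stage] = {"status": status, "time": time.time(), **info}
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    # ------------------------------------------------------------------
    def stage_simulate(self) -> None:
        truth = {}
        for name, g in self.cfg.group_configs().items():
            rng = self.rng(f"sim:{name}")
            ev = simulate_counts(g, "evoked", rng)
            sp = simulate_counts(g, "spontaneous", rng)
            frames = simulate_hunt_frames(g, rng)
            outcomes = simulate_capture_outcomes(g, rng)
            turns = simulate_turn_pairs(g, g.n_success_events, rng)
            pts = simulate_capture_points(g, g.n_success_events, rng)
            n_h = self.cfg.hierarchy_larvae
            epl = rng.integers(1, 7, size=n_h)
            hier = simulate_group_hierarchy(
                g,
                between_cov=np.diag(np.array([4.0, 0.08, 0.08]) ** 2),
                within_cov=np.diag(np.array([6.0, 0.12, 0.12]) ** 2),
                events_per_larva=epl,
                rng=rng,
            )
            # per-larva mean time-to-prey (s): lognormal around ~60 ms
            t_prey = np.exp(rng.normal(np.log(0.06), 0.25, size=g.n_larvae))

            summary = outcomes.assign(
                evoked_count=ev, spont_count=sp, hunt_frames=frames, t_prey_s=t_prey
            )
            summary.to_csv(self.out / f"{name}_larvae.csv", index=False)
            turns.to_csv(self.out / f"{name}_turns.csv", index=False)
            pts.to_csv(self.out / f"{name}_capture_points.csv", index=False)
            hier.to_csv(self.out / f"{name}_hierarchy_events.csv", index=False)
            truth[name] = {
                "evoked_rate_mean": g.rate_evoked[0] / g.rate_evoked[1],
                "spont_rate_mean": g.rate_spont[0] / g.rate_spont[1],
                "duration_mean_s": (
                    g.duration_nb[0] * (1 - g.duration_nb[1]) / g.duration_nb[1] / g.fps
                ),
                "attempt_mean": g.attempt_nb[0] * (1 - g.attempt_nb[1]) / g.attempt_nb[1],
                "p_success": g.p_success,
                "turn_slope": g.turn_slope,
                "p_fast": g.p_fast,
                "hier_mean": list(g.hier_mean),
            }
        (self.out / "truth.json").write_text(json.dumps(truth, indent=2))

    def _mcmc_kwargs(self, tag: str) -> dict:
        m = self.cfg.mcmc
        return dict(n_chains=m.chains, n_draws=m.draws, n_warmup=m.warmup, rng=self.rng(tag))

    def _load(self, name: str, suffix: str) -> pd.DataFrame:
        path = self.out / f"{name}_{suffix}.csv"
        if not path.exists():
            raise FileNotFoundError(
                f"stage input {path} missing: run the simulate stage first"
            )
        return pd.read_csv(path)

    def stage_fit_rates(self) -> None:
        for name in self.cfg.group_configs():
            df = self._load(name, "larvae")
            for cond, col in (("evoked", "evoked_count"), ("spontaneous", "spont_count")):
                post = counts_mod.fit_hunt_rate(
                    df[col].to_numpy(), **self._mcmc_kwargs(f"rates:{name}:{cond}")
                )
                post.to_frame().to_csv(self.out / f"{name}_{cond}_rate_draws.csv", index=False)
                self.posteriors[f"rate:{name}:{cond}"] = _summary_json(
                    post, ["r", "q", "lam"], self.out / f"{name}_{cond}_rate_summary.json"
                )

    def stage_fit_duration(self) -> None:
        for name, g in self.cfg.group_configs().items():
            df = self._load(name, "larvae")
            frames = df["hunt_frames"].to_numpy()
            frames = frames[frames > 0]  # exclusion rule: no-event larvae out
            post = counts_mod.fit_hunt_duration(
                frames, fps=g.fps, **self._mcmc_kwargs(f"duration:{name}")
            )
            self.posteriors[f"duration:{name}"] = _summary_json(
                post, ["mu_seconds"], self.out / f"{name}_duration_summary.json"
            )

    def stage_fit_capture(self) -> None:
        for name in self.cfg.group_configs():
            df = self._load(name, "larvae")
            df = df[df["attempts"] > 0]
            post = counts_mod.fit_capture_model(
                df["attempts"].to_numpy(),
                df["successes"].to_numpy(),
                **self._mcmc_kwargs(f"capture:{name}"),
            )
            post.to_frame().to_csv(self.out / f"{name}_capture_draws.csv", index=False)
            summ = _summary_json(
                post, ["mu_C", "p_s"], self.out / f"{name}_capture_summary.json"
            )
            cons = counts_mod.consumption_posterior(post)
            summ["consumption_mean"] = float(cons.mean())
            (self.out / f"{name}_capture_summary.json").write_text(json.dumps(summ, indent=2))
            self.posteriors[f"capture:{name}"] = summ

    def stage_fit_turn(self) -> None:
        for name in self.cfg.group_configs():
            df = self._load(name, "turns")
            post = turning_mod.fit_turn_model(
                df["theta_deg"], df["phi_deg"], **self._mcmc_kwargs(f"turn:{name}")
            )
            post.to_frame().to_csv(self.out / f"{name}_turn_draws.csv", index=False)
            summ = _summary_json(
                post, ["beta0", "beta1"], self.out / f"{name}_turn_summary.json"
            )
            summ["p_undershoot"] = turning_mod.undershoot_probability(post)
            (self.out / f"{name}_turn_summary.json").write_text(json.dumps(summ, indent=2))
            self.posteriors[f"turn:{name}"] = summ

    def stage_fit_mixture(self) -> None:
        for name in self.cfg.group_configs():
            df = self._load(name, "capture_points")
            fit = mixture_mod.fit_capture_mixture(
                df[["capture_speed_mm_s", "capture_distance_mm"]].to_numpy(),
                threshold=self.cfg.thresholds.membership,
                **self._mcmc_kwargs(f"mixture:{name}"),
            )
            df = df.assign(capture_class=fit.labels, membership=fit.membership)
            df.to_csv(self.out / f"{name}_capture_points_labelled.csv", index=False)
            summ = _summary_json(
                fit.posterior,
                ["mu_s_slow", "mu_s_fast", "mu_d_slow", "mu_d_fast"],
                self.out / f"{name}_mixture_summary.json",
            )
            summ["p_fast"] = fit.p_fast
            (self.out / f"{name}_mixture_summary.json").write_text(json.dumps(summ, indent=2))
            self.posteriors[f"mixture:{name}"] = summ

    def stage_fit_group(self) -> None:
        self.group_fits = {}
        for name in self.cfg.group_configs():
            df = self._load(name, "hierarchy_events")
            fit = groups_mod.fit_group_model(df, **self._mcmc_kwargs(f"group:{name}"))
            fit.posterior.to_frame().to_csv(self.out / f"{name}_group_draws.csv", index=False)
            self.posteriors[f"group:{name}"] = _summary_json(
                fit.posterior,
                [f"mu_{c}" for c in groups_mod.COMPONENTS],
                self.out / f"{name}_group_summary.json",
            )
            fit.larva_posterior_means().to_csv(
                self.out / f"{name}_larva_means.csv", index=False
            )
            self.group_fits[name] = fit

    def stage_pca(self) -> None:
        frames = []
        for name in self.cfg.group_configs():
            larvae = self._load(name, "larvae")
            means_path = self.out / f"{name}_larva_means.csv"
            if means_path.exists():  # model-estimated per-larva means
                means = pd.read_csv(means_path)
            else:  # fall back to empirical means
                ev = self._load(name, "hierarchy_events")
                means = ev.groupby("larva_id", as_index=False)[
                    ["capture_speed_mm_s", "capture_distance_mm", "turn_ratio"]
                ].mean()
            merged = larvae.merge(means, on="larva_id", how="inner").assign(group=name)
            frames.append(merged)
        table = pd.concat(frames, ignore_index=True)
        matrix = build_behavior_matrix(table, min_attempts=self.cfg.thresholds.min_attempts)
        emb = pca_embed(matrix)
        emb.scores.assign(
            group=table.set_index("larva_id").loc[emb.scores.index, "group"]
        ).to_csv(self.out / "pca_scores.csv")
        emb.loadings.to_csv(self.out / "pca_loadings.csv")
        pcr = pcr_efficiency(matrix, n_components=self.cfg.pcr_components,
                             seed=self.cfg.mcmc.seed)
        report = {
            "explained_variance_ratio": emb.explained_variance_ratio.tolist(),
            "pcr_components": pcr.n_components,
            "pcr_r2_insample": pcr.r2_insample,
            "pcr_rmsep": pcr.rmsep,
            "pcr_rmsep_cv": pcr.rmsep_cv,
        }
        (self.out / "pcr_report.json").write_text(json.dumps(report, indent=2))

    def stage_report(self) -> None:
        """Pairwise group comparisons across fitted posteriors, plus truth."""
        report: Dict[str, dict] = {"comparisons": {}}
        names = list(self.cfg.group_configs())

        def draws(path, col):
            f = self.out / path
            return pd.read_csv(f)[col].to_numpy() if f.exists() else None

        for a in names:
            for b in names:
                if a >= b:
                    continue
                comp = {}
                for label, path_tpl, col in (
                    ("rate_evoked", "{}_evoked_rate_draws.csv", "lam"),
                    ("p_success", "{}_capture_draws.csv", "p_s"),
                    ("turn_slope", "{}_turn_draws.csv", "beta1"),
                ):
                    da, db = draws(path_tpl.format(a), col), draws(path_tpl.format(b), col)
                    if da is not None and db is not None:
                        comp[f"P[{label}_{a}>{label}_{b}]"] = prob_greater(da, db)
                for c in groups_mod.COMPONENTS:
                    da = draws(f"{a}_group_draws.csv", f"mu_{c}")
                    db = draws(f"{b}_group_draws.csv", f"mu_{c}")
                    if da is not None and db is not None:
                        comp[f"P[mu_{c}_{a}>mu_{c}_{b}]"] = prob_greater(da, db)
                report["comparisons"][f"{a}_vs_{b}"] = comp
        truth_path = self.out / "truth.json"
        if truth_path.exists():
            report["ground_truth"] = json.loads(truth_path.read_text())
        report["posterior_summaries"] = self.posteriors
        (self.out / "report.json").write_text(json.dumps(report, indent=2))


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute the enabled stages in DAG order; return the manifest.

    Any stage failure halts downstream stages and is recorded in the
    manifest with the stage name.
    """
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    run = _Run(config)
    config.to_yaml(run.out / "config.yaml")
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        if run.done(stage) and not force:
            logger.info("stage %s already done; skipping", stage)
            continue
        logger.info("running stage %s", stage)
        try:
            getattr(run, f"stage_{stage}")()
        except Exception as exc:  # halt downstream stages
            run.mark(stage, "failed", error=str(exc))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        run.mark(stage, "done")
    return run.manifest
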