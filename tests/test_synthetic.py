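"""Generator tests: seeded determinism, moment consistency, structure."""

import numpy as np
import pandas as pd
import pytest

from zfhunt.kinematics import detect_hunt_events
from zfhunt.synthetic import (
    CaptureKinematics,
    GroupConfig,
    MixtureTruth,
    default_configs,
    simulate_capture_outcomes,
    simulate_capture_points,
    simulate_counts,
    simulate_group_hierarchy,
    simulate_trace,
    simulate_turn_pairs,
)


class TestCounts:
    def test_seeded_determinism(self, lf_config):
        a = simulate_counts(lf_config, "evoked")
        b = simulate_counts(lf_config, "evoked")
        np.testing.assert_array_equal(a, b)

    def test_poisson_limit(self):
        # alpha -> large with alpha/beta = 5 approaches Poisson(5)
        cfg = GroupConfig(group_label="LF", n_larvae=20000, rate_evoked=(1e6, 2e5), seed=4)
        c = simulate_counts(cfg, "evoked")
        assert abs(c.mean() - 5.0) < 3 * np.sqrt(5.0 / len(c))
        # variance close to mean (little overdispersion left)
        assert c.var() / c.mean() < 1.1

    def test_overdispersed_at_study_scale(self, lf_config):
        cfg = GroupConfig(**{**lf_config.to_dict(), "n_larvae": 60})
        c = simulate_counts(cfg, "evoked")
        mean = 13.3
        # NB sd with r=3: mean/sqrt(r) approx; allow 3 standard errors
        se = (mean / np.sqrt(3)) / np.sqrt(60)
        assert abs(c.mean() - mean) < 3 * se * np.sqrt(3)  # loose MC band
        assert c.var() > c.mean()  # Gamma mixing creates overdispersion

    def test_condition_selects_parameters(self, lf_config):
        cfg = GroupConfig(**{**lf_config.to_dict(), "n_larvae": 4000})
        ev = simulate_counts(cfg, "evoked")
        sp = simulate_counts(cfg, "spontaneous")
        assert ev.mean() > 2 * sp.mean()  # 13.3 vs 3.6

    def test_invalid_parameters_rejected(self, lf_config):
        d = lf_config.to_dict()
        d["rate_evoked"] = (-1.0, 0.2)
        with pytest.raises(ValueError):
            GroupConfig(**d)
        with pytest.raises(ValueError):
            simulate_counts(lf_config, "banana")


class TestCaptureOutcomes:
    @pytest.mark.parametrize("p,expect", [(0.0, "zero"), (1.0, "all")])
    def test_degenerate_success_probability(self, lf_config, p, expect):
        cfg = GroupConfig(**{**lf_config.to_dict(), "p_success": p})
        df = simulate_capture_outcomes(cfg)
        if expect == "zero":
            assert (df.successes == 0).all()
        else:
            assert (df.successes == df.attempts).all()

    def test_successes_bounded_by_attempts(self, configs):
        for cfg in configs.values():
            df = simulate_capture_outcomes(cfg)
            assert (df.successes <= df.attempts).all()

    def test_pooled_rate_matches_generating_probability(self, lf_config):
        cfg = GroupConfig(**{**lf_config.to_dict(), "n_larvae": 60, "seed": 9})
        df = simulate_capture_outcomes(cfg)
        pooled = df.successes.sum() / df.attempts.sum()
        se = np.sqrt(0.32 * 0.68 / df.attempts.sum())
        assert abs(pooled - 0.32) < 4 * se


class TestTurnPairs:
    def test_noiseless_identity(self, lf_config):
        cfg = GroupConfig(
            **{**lf_config.to_dict(), "turn_noise_sd": 0.0, "turn_slope": 1.0, "turn_intercept": 0.0}
        )
        df = simulate_turn_pairs(cfg, 50)
        np.testing.assert_allclose(df.phi_deg, df.theta_deg)

    def test_ols_consistency(self, lf_config):
        # closed-form OLS on a large sample recovers the generating slope
        df = simulate_turn_pairs(lf_config, 10_000, np.random.default_rng(3))
        slope = np.polyfit(df.theta_deg, df.phi_deg, 1)[0]
        assert abs(slope - 0.73) < 0.02

    def test_azimuths_bimodal_and_symmetric(self, lf_config):
        df = simulate_turn_pairs(lf_config, 5000, np.random.default_rng(4))
        a = df.theta_deg.abs()
        assert ((a >= 35) & (a <= 50)).all()
        frac_left = (df.theta_deg < 0).mean()
        assert abs(frac_left - 0.5) < 0.05


class TestCapturePoints:
    def test_all_fast_when_p_one(self, lf_config):
        cfg = GroupConfig(**{**lf_config.to_dict(), "p_fast": 1.0})
        df = simulate_capture_points(cfg, 40)
        assert (df.true_label == "fast").all()

    def test_fast_cluster_correlation(self, lf_config):
        cfg = GroupConfig(
            **{
                **lf_config.to_dict(),
                "mixture": MixtureTruth(rho_fast=0.8),
                "p_fast": 0.5,
                "seed": 6,
            }
        )
        df = simulate_capture_points(cfg, 10_000)
        fast = df[df.true_label == "fast"]
        r = np.corrcoef(fast.capture_speed_mm_s, fast.capture_distance_mm)[0, 1]
        assert abs(r - 0.8) < 0.03

    def test_cluster_ordering_enforced(self):
        with pytest.raises(ValueError):
            MixtureTruth(slow_mean=(30.0, 0.2), fast_mean=(20.0, 0.4))


class TestGroupHierarchy:
    def test_within_zero_collapses_to_larva_means(self, lf_config, rng):
        bc = np.diag([4.0, 0.08, 0.08]) ** 2
        df = simulate_group_hierarchy(lf_config, bc, np.zeros((3, 3)), [3, 3, 3], rng)
        for _, g in df.groupby("larva_id"):
            assert g[["capture_speed_mm_s", "capture_distance_mm", "turn_ratio"]].std().max() < 1e-9

    def test_law_of_large_numbers(self, lf_config):
        bc = np.diag(np.array([4.0, 0.08, 0.08]) ** 2)
        wc = np.diag(np.array([6.0, 0.12, 0.12]) ** 2)
        df = simulate_group_hierarchy(
            lf_config, bc, wc, np.full(2000, 2), np.random.default_rng(8)
        )
        means = df.attrs["larva_means"].mean(axis=0)
        se = np.array([4.0, 0.08, 0.08]) / np.sqrt(2000)
        np.testing.assert_array_less(np.abs(means - np.array([28.2, 0.35, 0.85])), 4 * se)

    def test_non_psd_covariance_rejected(self, lf_config, rng):
        bad = np.array([[1, 2, 0], [2, 1, 0], [0, 0, 1.0]])  # eigenvalue -1
        with pytest.raises(ValueError):
            simulate_group_hierarchy(lf_config, bad, np.eye(3), [2, 2, 2], rng)


class TestTrace:
    def test_zero_events_detects_nothing(self):
        tr = simulate_trace([], 5.0)
        assert detect_hunt_events(tr) == []

    def test_constructed_events_detected(self):
        events = [(1.0, 0.5), (3.0, 0.5), (5.0, 0.5), (7.0, 0.5), (9.0, 0.5)]
        tr = simulate_trace(events, 11.0, seed=2)
        assert len(detect_hunt_events(tr)) == 5

    def test_close_events_concatenated(self):
        # separated by 0.5 s = 205 frames < 300 -> one merged event
        tr = simulate_trace([(1.0, 0.5), (2.0, 0.5)], 4.0, seed=3)
        assert len(detect_hunt_events(tr)) == 1

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError):
            simulate_trace([(1.0, 1.0), (1.5, 1.0)], 5.0)
        with pytest.raises(ValueError):
            simulate_trace([(4.8, 0.5)], 5.0)

    def test_determinism_under_seed(self):
        a = simulate_trace([(1.0, 0.8)], 3.0, seed=11, kinematics=CaptureKinematics())
        b = simulate_trace([(1.0, 0.8)], 3.0, seed=11, kinematics=CaptureKinematics())
        np.testing.assert_array_equal(a.left_eye_deg, b.left_eye_deg)
        np.testing.assert_array_equal(a.head_x_mm, b.head_x_mm)
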