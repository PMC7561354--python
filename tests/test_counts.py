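"""Count-model tests against conjugate and grid-quadrature oracles."""

import numpy as np
import pytest
from scipy import stats

from zfhunt.counts import (
    LarvaSummary,
    consumption_posterior,
    efficiency_and_hpi,
    fit_capture_model,
    fit_hunt_duration,
    fit_hunt_rate,
    nb_posterior_grid,
    prob_greater,
)
from zfhunt.synthetic import GroupConfig, default_configs, simulate_counts

from conftest import FAST_MCMC


class TestHuntRate:
    def test_grid_quadrature_oracle(self):
        # posterior means from MCMC match 2-D numerical integration
        counts = np.array([3, 5, 2, 8, 4, 6, 1, 7, 0, 5])
        r_g, q_g, lam_g = nb_posterior_grid(counts)
        post = fit_hunt_rate(counts, seed=3, n_draws=4000, n_warmup=1500)
        assert post.mean("lam") == pytest.approx(lam_g, rel=0.02)
        assert post.mean("r") == pytest.approx(r_g, rel=0.05)
        assert post.mean("q") == pytest.approx(q_g, rel=0.05)

    def test_degenerate_concentration(self):
        # all larvae with the same large count: lam concentrates there
        counts = np.full(400, 12)
        post = fit_hunt_rate(counts, seed=4, **FAST_MCMC)
        assert post.mean("lam") == pytest.approx(12.0, rel=0.03)

    def test_all_zero_counts_supported(self):
        post = fit_hunt_rate(np.zeros(30, dtype=int), seed=5, **FAST_MCMC)
        assert post.mean("lam") < 0.5  # posterior mass near zero rate

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_hunt_rate(np.array([3, -1, 2]))

    def test_permutation_invariance(self, rng):
        counts = rng.poisson(8, size=40)
        a = fit_hunt_rate(counts, seed=6, **FAST_MCMC).mean("lam")
        b = fit_hunt_rate(counts[::-1].copy(), seed=6, **FAST_MCMC).mean("lam")
        assert a == pytest.approx(b, abs=1e-12)  # same data order-independent

    def test_gamma_mixing_recovery(self, lf_config):
        # alpha = r and beta = q/(1-q) recover the generating Gamma mixture
        cfg = GroupConfig(**{**lf_config.to_dict(), "n_larvae": 4000, "seed": 21})
        counts = simulate_counts(cfg, "evoked")
        post = fit_hunt_rate(counts, seed=7, **FAST_MCMC)
        alpha = post.mean("r")
        beta = np.mean(post.get("q") / (1 - post.get("q")))
        assert alpha == pytest.approx(3.0, rel=0.15)
        assert alpha / beta == pytest.approx(13.3, rel=0.05)


class TestHuntDuration:
    def test_frames_convert_to_seconds(self):
        frames = np.full(300, 4100)
        post = fit_hunt_duration(frames, fps=410.0, seed=8, **FAST_MCMC)
        assert post.mean("mu_seconds") == pytest.approx(10.0, rel=0.03)

    def test_zero_frames_rejected_with_exclusion_hint(self):
        with pytest.raises(ValueError, match="exclude"):
            fit_hunt_duration(np.array([0, 4100, 2000]))


class TestCaptureModel:
    def test_conjugate_beta_oracle(self, rng):
        # conditional p_s posterior is exactly Beta(1+sum Ns, 1+sum(h-Ns))
        h = rng.integers(1, 20, size=50)
        ns = rng.binomial(h, 0.3)
        post = fit_capture_model(h, ns, seed=9, **FAST_MCMC)
        a, b = 1 + ns.sum(), 1 + (h - ns).sum()
        exact = stats.beta(a, b)
        draws = post.get("p_s")
        assert draws.mean() == pytest.approx(exact.mean(), rel=0.01)
        assert draws.var(ddof=1) == pytest.approx(exact.var(), rel=0.15)

    def test_all_successes_closed_form(self):
        h = np.array([4, 6, 2, 8])
        post = fit_capture_model(h, h, seed=10, **FAST_MCMC)
        expected = (1 + h.sum()) / (2 + h.sum())
        assert post.mean("p_s") == pytest.approx(expected, rel=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_capture_model([5, 5], [6, 1])
        with pytest.raises(ValueError):
            fit_capture_model([5, 0], [1, 0])

    def test_consumption_zero_when_no_successes(self):
        h = np.array([5, 8, 3, 9, 6, 7])
        post = fit_capture_model(h, np.zeros_like(h), seed=11, **FAST_MCMC)
        cons = consumption_posterior(post)
        assert np.all(cons >= 0)
        assert cons.mean() < 0.2 * post.mean("mu_C")

    def test_consumption_independence_diagnostic(self, rng):
        h = rng.integers(1, 25, size=60)
        ns = rng.binomial(h, 0.32)
        post = fit_capture_model(h, ns, seed=12, **FAST_MCMC)
        cons = consumption_posterior(post)
        # mu_C and p_s are sampled independently given the data, so the mean
        # of products equals the product of means within Monte Carlo error
        prod = post.mean("mu_C") * post.mean("p_s")
        assert cons.mean() == pytest.approx(prod, rel=0.02)

    def test_missing_parameters_contract_error(self):
        post = fit_hunt_rate(np.array([1, 2, 3, 4, 5]), seed=13, **FAST_MCMC)
        with pytest.raises(ValueError):
            consumption_posterior(post)


class TestEfficiencyHPI:
    def make(self, larva_id, h, ns):
        return LarvaSummary(larva_id=larva_id, attempts=h, successes=ns)

    def test_basic_values(self):
        df = efficiency_and_hpi([self.make("a", 10, 5), self.make("b", 3, 0)])
        a = df.set_index("larva_id")
        assert a.loc["a", "efficiency"] == 0.5
        assert a.loc["a", "hpi"] == 2.5
        assert a.loc["b", "efficiency"] == 0.0 and a.loc["b", "hpi"] == 0.0

    def test_hpi_separates_equal_efficiency(self):
        # 1/2 and 5/10 share efficiency but differ in hunt power
        df = efficiency_and_hpi([self.make("a", 2, 1), self.make("b", 10, 5)])
        a = df.set_index("larva_id")
        assert a.loc["a", "efficiency"] == a.loc["b", "efficiency"]
        assert a.loc["a", "hpi"] == 0.5 and a.loc["b", "hpi"] == 2.5

    def test_zero_attempt_larvae_excluded(self):
        df = efficiency_and_hpi([self.make("a", 0, 0), self.make("b", 5, 2)])
        assert list(df.larva_id) == ["b"]


class TestProbGreater:
    def test_strict_dominance(self):
        b = np.arange(100.0)
        assert prob_greater(b + 1, b) == 1.0

    def test_symmetric_same_distribution(self, rng):
        a, b = rng.normal(size=20000), rng.normal(size=20000)
        assert prob_greater(a, b) == pytest.approx(0.5, abs=0.02)

    def test_ties_count_half(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert prob_greater(a, a) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prob_greater(np.array([]), np.array([1.0]))

    def test_unequal_lengths_cycled(self):
        assert prob_greater(np.array([2.0]), np.array([1.0, 1.0, 1.0])) == 1.0
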