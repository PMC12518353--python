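"""Allocation policies, estimate generation and the synthetic experiment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from skewsample import (
    CONDITIONS,
    NEGATIVE,
    UNIFORM,
    AgentParams,
    BinnedDistribution,
    ExperimentDesign,
    PopulationParams,
    bin_probabilities,
    expected_sampling_bias,
    generate_estimate,
    mixture_probs,
    sample_allocation,
    simulate_experiment,
    stratified_allocation,
)
from conftest import build_trial


class TestMixtureProbs:
    def test_pure_objective_histogram(self):
        g = bin_probabilities(NEGATIVE)
        np.testing.assert_allclose(mixture_probs(g, 0.0), g, atol=1e-15)

    def test_pure_uniform(self):
        g = bin_probabilities(NEGATIVE)
        np.testing.assert_allclose(mixture_probs(g, 1.0), np.full(5, 0.2), atol=1e-15)

    def test_fitted_weight_reproduces_reported_rare_bin_share(self):
        # f1 = 0.49*0.008 + 0.51*0.2 = 0.10592 -> 11% rare-bin allocation
        g = bin_probabilities(NEGATIVE)
        f1 = mixture_probs(g, 0.51)[0]
        assert f1 == pytest.approx(0.10592, abs=1e-12)

    def test_invalid_weight_rejected(self):
        g = bin_probabilities(UNIFORM)
        with pytest.raises(ValueError):
            mixture_probs(g, 1.2)
        with pytest.raises(ValueError):
            mixture_probs(g, -0.1)

    @settings(deadline=None)
    @given(
        w=st.floats(min_value=0.0, max_value=1.0),
        label=st.sampled_from(["negative", "positive", "uniform"]),
    )
    def test_simplex_and_between_bounds(self, w, label):
        from skewsample import ShapeCondition

        g = bin_probabilities(ShapeCondition.from_label(label))
        f = mixture_probs(g, w)
        assert abs(f.sum() - 1.0) < 1e-12
        assert np.all(f >= np.minimum(g, 0.2) - 1e-12)
        assert np.all(f <= np.maximum(g, 0.2) + 1e-12)


class TestStratifiedAllocation:
    def test_uniform_exact_quotas(self):
        np.testing.assert_array_equal(
            stratified_allocation(bin_probabilities(UNIFORM), 10), [2, 2, 2, 2, 2]
        )

    def test_negative_budget_10(self):
        # quotas (0.08, 0.56, 1.52, 2.96, 4.88): remainders promote bins 4, 5, 2
        np.testing.assert_array_equal(
            stratified_allocation(bin_probabilities(NEGATIVE), 10), [0, 1, 1, 3, 5]
        )

    def test_negative_budget_20(self):
        np.testing.assert_array_equal(
            stratified_allocation(bin_probabilities(NEGATIVE), 20), [0, 1, 3, 6, 10]
        )

    @pytest.mark.parametrize("condition", CONDITIONS, ids=lambda c: c.label)
    @pytest.mark.parametrize("budget", [10, 20])
    def test_minimizes_total_absolute_deviation(self, condition, budget):
        """Largest-remainder output attains the exhaustive-search optimum."""
        g = bin_probabilities(condition)
        counts = stratified_allocation(g, budget)
        achieved = np.abs(counts - budget * g).sum()
        best = min(
            np.abs(np.array(c) - budget * g).sum()
            for c in itertools.product(range(budget + 1), repeat=4)
            if sum(c) <= budget
            for c in [(*c, budget - sum(c))]
        )
        assert achieved == pytest.approx(best, abs=1e-12)

    def test_invalid_budget(self):
        with pytest.raises(ValueError):
            stratified_allocation(bin_probabilities(UNIFORM), 0)


class TestSampleAllocation:
    def test_deterministic_policy_ignores_seed(self, rng):
        g = bin_probabilities(NEGATIVE)
        a = sample_allocation("stratified-deterministic", g, 10, np.random.default_rng(1))
        b = sample_allocation("stratified-deterministic", g, 10, np.random.default_rng(99))
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(a, stratified_allocation(g, 10))

    def test_counts_sum_to_budget(self, rng):
        g = bin_probabilities(NEGATIVE)
        for policy, w in [("stratified-random", None), ("mixture", 0.3)]:
            counts = sample_allocation(policy, g, 20, rng, w=w)
            assert counts.sum() == 20 and np.all(counts >= 0)

    def test_mixture_w0_law_of_large_numbers(self, rng):
        g = bin_probabilities(NEGATIVE)
        pooled = sample_allocation("mixture", g, 1_000_000, rng, w=0.0)
        freq = pooled / pooled.sum()
        se = np.sqrt(g * (1 - g) / 1_000_000)
        assert np.all(np.abs(freq - g) < 4 * se)

    def test_mixture_w1_uniform_frequencies(self, rng):
        g = bin_probabilities(NEGATIVE)
        pooled = sample_allocation("mixture", g, 200_000, rng, w=1.0)
        np.testing.assert_allclose(pooled / pooled.sum(), 0.2, atol=0.005)

    def test_unknown_policy_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_allocation("greedy", bin_probabilities(UNIFORM), 10, rng)

    def test_mixture_requires_weight(self, rng):
        with pytest.raises(ValueError):
            sample_allocation("mixture", bin_probabilities(UNIFORM), 10, rng)


class TestGenerateEstimate:
    def test_no_adjustment_returns_experienced_mean(self, rng):
        trial = build_trial(condition="negative", counts=(0, 1, 1, 3, 5))
        dist = BinnedDistribution.from_condition(NEGATIVE, trial.multiplier)
        agent = AgentParams(w=0.5, kappa=0.0, sigma_e=0.0)
        est = generate_estimate(trial, agent, dist, rng)
        assert est == pytest.approx(trial.draw_values.mean() * trial.multiplier, abs=1e-12)

    def test_uniform_condition_has_no_correction(self, rng):
        trial = build_trial(condition="uniform", counts=(2, 2, 2, 2, 2))
        dist = BinnedDistribution.from_condition(UNIFORM, trial.multiplier)
        agent = AgentParams(w=0.7, kappa=1.0, sigma_e=0.0)
        est = generate_estimate(trial, agent, dist, rng)
        assert est == pytest.approx(trial.draw_values.mean() * trial.multiplier, abs=1e-12)

    def test_full_correction_negative_condition(self, rng):
        """kappa=1 shifts the estimate up by the analytic expected bias magnitude."""
        trial = build_trial(condition="negative", counts=(1, 1, 2, 3, 3))
        dist = BinnedDistribution.from_condition(NEGATIVE, trial.multiplier)
        agent = AgentParams(w=0.5, kappa=1.0, sigma_e=0.0)
        est_norm = generate_estimate(trial, agent, dist, rng) / trial.multiplier

        # independent oracle: f from the mixture equation, m by numerical integration
        g = np.diff(np.linspace(0, 1, 6) ** 3)
        f = 0.5 * g + 0.5 * 0.2
        edges = np.linspace(0, 1, 6)
        m = np.array(
            [
                integrate.quad(lambda x: x * 3 * x**2, edges[k], edges[k + 1])[0] / g[k]
                for k in range(5)
            ]
        )
        correction = -(f @ m - 0.75)
        assert correction == pytest.approx(0.1148, abs=5e-4)
        expected = np.clip(trial.draw_values.mean() + correction, 0, 1)
        assert est_norm == pytest.approx(expected, abs=1e-10)

    def test_empty_trial_rejected(self, rng):
        trial = build_trial(counts=(0, 1, 1, 3, 5))
        trial.draw_values = np.empty(0)
        trial.draw_bins = np.empty(0, dtype=int)
        dist = BinnedDistribution.from_condition(NEGATIVE, trial.multiplier)
        with pytest.raises(ValueError):
            generate_estimate(trial, AgentParams(0.5), dist, rng)


class TestExpectedSamplingBias:
    @pytest.mark.parametrize("w", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_monte_carlo_experienced_mean_converges(self, w, rng):
        """Mean experienced mean under mixture(w) matches sum_k f_k m_k."""
        dist = BinnedDistribution.from_condition(NEGATIVE, 50.0)
        f = mixture_probs(dist.g, w)
        n_trials, budget = 100_000, 10
        counts = rng.multinomial(budget, f, size=n_trials)
        # conditional expectation of the experienced mean given counts
        cond_means = counts @ dist.m / budget
        expected = float(f @ dist.m)
        se = cond_means.std(ddof=1) / np.sqrt(n_trials)
        assert abs(cond_means.mean() - expected) < 4 * max(se, 1e-12)
        assert expected - dist.mu == pytest.approx(expected_sampling_bias(dist, w), abs=1e-12)


class TestSimulateExperiment:
    def test_bookkeeping(self):
        design = ExperimentDesign(n_participants=20, budget_split=0.5, seed=5)
        records = simulate_experiment(design, PopulationParams(0.5, 0.2))
        assert len(records) == 20 * 12
        by_pid = {}
        for r in records:
            by_pid.setdefault(r.participant_id, []).append(r)
        assert len(by_pid) == 20
        budgets = {trials[0].budget for trials in by_pid.values()}
        assert budgets == {10, 20}
        n_small = sum(1 for t in by_pid.values() if t[0].budget == 10)
        assert n_small == 10
        for trials in by_pid.values():
            assert [t.trial_index for t in trials] == list(range(1, 13))
            # three condition blocks of four consecutive trials
            labels = [t.condition for t in trials]
            assert sorted(set(labels)) == ["negative", "positive", "uniform"]
            for start in (0, 4, 8):
                assert len(set(labels[start : start + 4])) == 1
            for t in trials:
                t.validate()

    def test_reproducible_under_seed(self):
        design = ExperimentDesign(n_participants=5, seed=123)
        a = simulate_experiment(design, PopulationParams(0.4, 0.1))
        b = simulate_experiment(design, PopulationParams(0.4, 0.1))
        assert [r.estimate_raw for r in a] == [r.estimate_raw for r in b]
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.counts, rb.counts)

    def test_degenerate_objective_population(self):
        """mu_w ~ 0: pooled negative-condition bin-1 share approaches g_1."""
        design = ExperimentDesign(n_participants=50, budget_split=0.0, seed=9)
        records = simulate_experiment(design, PopulationParams(1e-9, 1e-9), sigma_e=0.0)
        neg = [r for r in records if r.condition == "negative"]
        pooled = np.sum([r.counts for r in neg], axis=0)
        share = pooled[0] / pooled.sum()
        se = np.sqrt(0.008 * 0.992 / pooled.sum())
        assert abs(share - 0.008) < 4 * se

    def test_degenerate_uniform_population(self):
        """mu_w ~ 1: every bin receives about a fifth of the samples."""
        design = ExperimentDesign(n_participants=50, budget_split=0.0, seed=9)
        records = simulate_experiment(
            design, PopulationParams(1 - 1e-9, 1e-9), sigma_e=0.0
        )
        for label in ("negative", "positive", "uniform"):
            sub = [r for r in records if r.condition == label]
            pooled = np.sum([r.counts for r in sub], axis=0)
            np.testing.assert_allclose(pooled / pooled.sum(), 0.2, atol=0.02)

    def test_agent_params_validation(self):
        with pytest.raises(ValueError):
            AgentParams(w=1.5)
        with pytest.raises(ValueError):
            AgentParams(w=0.5, kappa=2.0)
        with pytest.raises(ValueError):
            AgentParams(w=0.5, sigma_e=-0.1)
        with pytest.raises(ValueError):
            PopulationParams(0.5, 0.0)
        with pytest.raises(ValueError):
            ExperimentDesign(n_participants=0)
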