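"""Simulated sampling agents and synthetic experiments.

An agent allocates a fixed budget of N samples over the five histogram bins.
Three allocation policies are provided:

* ``stratified-deterministic`` — proportional allocation with largest-remainder
  (Hamilton) rounding of the quotas N·g_k; the unbiased benchmark strategy.
* ``stratified-random`` — Multinomial(N, g); the null model for the pooled
  binomial tests (equivalent to simple random sampling from the distribution).
* ``mixture`` — the cognitive-fencing policy Multinomial(N, f(w)) with
  f_k(w) = (1−w)·g_k + w/5: a weight-w blend of the objective histogram and a
  uniform, range-covering component.

Estimates are generated as partially bias-corrected experienced means: the
agent reports its experienced mean minus ``kappa`` times the analytic expected
sampling bias of its own policy, plus Gaussian reporting noise ``sigma_e``.
A full synthetic experiment mirrors the study design: between-subject budgets
of 10 or 20 samples, three within-subject shape conditions presented in
randomized block order with four trials each, and participant-level mixture
weights drawn from a truncated Normal(mu_w, sigma_w) population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .stimuli import (
    CONDITIONS,
    DEFAULT_N_BINS,
    BinnedDistribution,
    ShapeCondition,
    bin_quantile,
    make_trial_stimulus,
)

__all__ = [
    "AgentParams",
    "PopulationParams",
    "TrialRecord",
    "ExperimentDesign",
    "mixture_probs",
    "stratified_allocation",
    "sample_allocation",
    "expected_sampling_bias",
    "generate_estimate",
    "simulate_experiment",
    "DEFAULT_KAPPA",
    "DEFAULT_SIGMA_E",
]

BUDGETS = (10, 20)

# Study-condition defaults for the estimate-generation model: agents correct
# about half of their expected sampling bias and report with ~5 points of noise
# on the 0-100 positivity scale.
DEFAULT_KAPPA = 0.5
DEFAULT_SIGMA_E = 0.05


@dataclass(frozen=True)
class AgentParams:
    """A simulated participant: mixture weight, bias correction, report noise."""

    w: float
    kappa: float = DEFAULT_KAPPA
    sigma_e: float = DEFAULT_SIGMA_E

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"mixture weight w must lie in [0, 1], got {self.w}")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must lie in [0, 1], got {self.kappa}")
        if self.sigma_e < 0.0:
            raise ValueError(f"sigma_e must be >= 0, got {self.sigma_e}")


@dataclass(frozen=True)
class PopulationParams:
    """Population distribution of the mixture weight: TruncNormal(mu_w, sigma_w) on [0,1]."""

    mu_w: float = 0.51
    sigma_w: float = 0.22

    def __post_init__(self) -> None:
        if self.sigma_w <= 0.0:
            raise ValueError(f"sigma_w must be > 0, got {self.sigma_w}")

    def sample_weights(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (0.0 - self.mu_w) / self.sigma_w
        b = (1.0 - self.mu_w) / self.sigma_w
        return stats.truncnorm.rvs(
            a, b, loc=self.mu_w, scale=self.sigma_w, size=n, random_state=rng
        )


@dataclass
class TrialRecord:
    """One trial: allocation counts, normalized draw values, and the raw estimate."""

    participant_id: str
    condition: str
    budget: int
    counts: np.ndarray
    draw_bins: np.ndarray  # 1-based bin index per draw
    draw_values: np.ndarray  # normalized [0, 1] values, aligned with draw_bins
    multiplier: float
    estimate_raw: float
    trial_index: int

    @property
    def draws(self) -> list[tuple[int, float, float]]:
        """Draws as (bin index, normalized value, raw value) tuples."""
        return [
            (int(k), float(v), float(v * self.multiplier))
            for k, v in zip(self.draw_bins, self.draw_values)
        ]

    @property
    def estimate_normalized(self) -> float:
        return self.estimate_raw / self.multiplier

    def validate(self, n_bins: int = DEFAULT_N_BINS) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (n_bins,) or np.any(counts < 0):
            raise ValueError(f"counts must be {n_bins} non-negative integers")
        if int(counts.sum()) != self.budget:
            raise ValueError(
                f"counts sum {int(counts.sum())} does not match budget {self.budget}"
            )
        if len(self.draw_bins) != self.budget or len(self.draw_values) != self.budget:
            raise ValueError("number of draws must equal the budget")
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        for k, v in zip(self.draw_bins, self.draw_values):
            lo, hi = edges[k - 1], edges[k]
            inside = (lo <= v < hi) or (k == n_bins and lo <= v <= hi)
            if not inside:
                raise ValueError(
                    f"draw value {v} outside bin {k} interval [{lo}, {hi})"
                )
        bin_counts = np.bincount(self.draw_bins, minlength=n_bins + 1)[1:]
        if not np.array_equal(bin_counts, counts):
            raise ValueError("per-bin draw tallies do not match counts")
        if not 0.0 <= self.estimate_raw <= self.multiplier:
            raise ValueError(
                f"estimate {self.estimate_raw} outside [0, {self.multiplier}]"
            )


@dataclass(frozen=True)
class ExperimentDesign:
    """Bookkeeping for one synthetic experiment."""

    n_participants: int = 145
    budget_split: float = 0.5  # fraction assigned to the 10-sample arm
    trials_per_condition: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if not 0.0 <= self.budget_split <= 1.0:
            raise ValueError("budget_split must lie in [0, 1]")


def mixture_probs(g: np.ndarray, w: float) -> np.ndarray:
    """Cognitive-fencing allocation probabilities f_k = (1−w)·g_k + w/K."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"mixture weight w must lie in [0, 1], got {w}")
    g = np.asarray(g, dtype=float)
    return (1.0 - w) * g + w / g.size


def stratified_allocation(g: np.ndarray, budget: int) -> np.ndarray:
    """Deterministic proportional allocation with largest-remainder rounding.

    Quotas budget·g_k are floored; leftover samples go to the bins with the
    largest fractional remainders, ties broken toward the lower bin index.
    """
    if budget < 1:
        raise ValueError(f"budget must be >= 1, got {budget}")
    g = np.asarray(g, dtype=float)
    quotas = budget * g
    counts = np.floor(quotas).astype(int)
    remainders = quotas - counts
    short = budget - int(counts.sum())
    # stable sort on -remainder keeps lower bin index first among ties
    order = np.argsort(-remainders, kind="stable")
    counts[order[:short]] += 1
    return counts


def sample_allocation(
    policy: str,
    g: np.ndarray,
    budget: int,
    rng: np.random.Generator,
    w: float | None = None,
) -> np.ndarray:
    """Allocate ``budget`` samples over bins under the named policy."""
    if policy == "stratified-deterministic":
        return stratified_allocation(g, budget)
    if policy == "stratified-random":
        return rng.multinomial(budget, np.asarray(g, dtype=float))
    if policy == "mixture":
        if w is None:
            raise ValueError("mixture policy requires a weight w")
        return rng.multinomial(budget, mixture_probs(g, w))
    raise ValueError(
        f"unknown policy {policy!r}; expected 'stratified-deterministic', "
        "'stratified-random' or 'mixture'"
    )


def expected_sampling_bias(dist: BinnedDistribution, w: float) -> float:
    """Analytic expected experienced-mean bias sum_k f_k(w)·m_k − mu under mixture(w)."""
    f = mixture_probs(dist.g, w)
    return float(f @ dist.m - dist.mu)


def _draw_trial_values(
    dist: BinnedDistribution, counts: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw normalized values for a counts vector, bin by bin."""
    bins: list[int] = []
    values: list[np.ndarray] = []
    for k, c in enumerate(counts, start=1):
        if c > 0:
            bins.extend([k] * int(c))
            values.append(
                np.atleast_1d(bin_quantile(dist, k, rng.random(int(c)), normalized=True))
            )
    draw_bins = np.array(bins, dtype=int)
    draw_values = np.concatenate(values) if values else np.empty(0)
    return draw_bins, draw_values


def generate_estimate(
    trial: TrialRecord,
    agent: AgentParams,
    dist: BinnedDistribution,
    rng: np.random.Generator,
) -> float:
    """Partially bias-corrected experienced mean with Gaussian noise, raw scale.

    estimate = experienced_mean − kappa · E[bias | policy mixture(w)] + eps,
    eps ~ Normal(0, sigma_e), clamped to [0, 1] then scaled by the multiplier.
    """
    if len(trial.draw_values) == 0:
        raise ValueError("cannot generate an estimate for a trial with no draws")
    experienced = float(np.mean(trial.draw_values))
    correction = agent.kappa * expected_sampling_bias(dist, agent.w)
    noise = rng.normal(0.0, agent.sigma_e) if agent.sigma_e > 0 else 0.0
    est = np.clip(experienced - correction + noise, 0.0, 1.0)
    return float(est * dist.multiplier)


def simulate_experiment(
    design: ExperimentDesign,
    pop: PopulationParams | None = None,
    kappa: float = DEFAULT_KAPPA,
    sigma_e: float = DEFAULT_SIGMA_E,
    return_agents: bool = False,
):
    """Simulate a full experiment with the study's design structure.

    Each participant receives one budget arm (the first ``floor(split·n)``
    participants after a seeded shuffle get 10 samples), one mixture weight
    drawn from the population, and ``3 × trials_per_condition`` trials in
    randomized condition-block order.  Fully reproducible from ``design.seed``.

    Returns the trial records; with ``return_agents`` also a dict mapping
    participant id to the :class:`AgentParams` used (the generative truth,
    for recovery studies).
    """
    pop = pop or PopulationParams()
    rng = np.random.default_rng(design.seed)
    n = design.n_participants

    shuffled = rng.permutation(n)
    n_small = int(np.floor(design.budget_split * n))
    budgets = np.full(n, BUDGETS[1], dtype=int)
    budgets[shuffled[:n_small]] = BUDGETS[0]
    weights = pop.sample_weights(n, rng)

    width = max(3, len(str(n)))
    records: list[TrialRecord] = []
    agents: dict[str, AgentParams] = {}
    for i in range(n):
        agent = AgentParams(w=float(weights[i]), kappa=kappa, sigma_e=sigma_e)
        pid = f"p{i + 1:0{width}d}"
        agents[pid] = agent
        block_order = rng.permutation(len(CONDITIONS))
        trial_index = 1
        for cidx in block_order:
            condition: ShapeCondition = CONDITIONS[cidx]
            for _ in range(design.trials_per_condition):
                dist = make_trial_stimulus(condition, rng)
                counts = sample_allocation(
                    "mixture", dist.g, int(budgets[i]), rng, w=agent.w
                )
                draw_bins, draw_values = _draw_trial_values(dist, counts, rng)
                trial = TrialRecord(
                    participant_id=pid,
                    condition=condition.label,
                    budget=int(budgets[i]),
                    counts=counts,
                    draw_bins=draw_bins,
                    draw_values=draw_values,
                    multiplier=dist.multiplier,
                    estimate_raw=0.0,
                    trial_index=trial_index,
                )
                trial.estimate_raw = generate_estimate(trial, agent, dist, rng)
                trial.validate()
                records.append(trial)
                trial_index += 1
    if return_agents:
        return records, agents
    return records
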