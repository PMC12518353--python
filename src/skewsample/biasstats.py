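"""Bias statistics, exclusion rules, binomial tests and bootstrap summaries.

Definitions (all on the normalized [0, 1] scale):

* experienced mean      — average of the values actually drawn in a trial;
* sampling bias         — experienced mean − true mean;
* estimation deviation  — reported estimate − true mean;
* estimation adjustment — experienced mean − reported estimate.

The three statistics satisfy the identity
``sampling_bias = estimation_deviation + estimation_adjustment`` exactly.
Pooled exact binomial tests compare per-bin allocation shares against the
stratified-sampling expectation (the bin probability g_k); condition × budget
summaries use participant-clustered percentile bootstrap intervals.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .stimuli import BinnedDistribution, ShapeCondition

logger = logging.getLogger(__name__)

__all__ = [
    "TrialStatistics",
    "BiasSummary",
    "ProportionTest",
    "ExclusionReport",
    "apply_exclusions",
    "experienced_mean",
    "trial_statistics",
    "pooled_bin_test",
    "condition_summaries",
    "stratified_efficiency",
    "StratifiedEfficiency",
    "payoff_loss",
]


@dataclass(frozen=True)
class TrialStatistics:
    sampling_bias: float
    estimation_deviation: float
    estimation_adjustment: float


@dataclass(frozen=True)
class BiasSummary:
    """Per condition × budget aggregate of the three trial statistics."""

    condition: str
    budget: int
    mean_sampling_bias: float
    mean_estimation_deviation: float
    mean_estimation_adjustment: float
    ci_sampling_bias: tuple[float, float]
    ci_estimation_deviation: tuple[float, float]
    ci_estimation_adjustment: tuple[float, float]
    n_trials: int


@dataclass(frozen=True)
class ProportionTest:
    """Exact binomial test of a pooled per-bin allocation share."""

    bin_index: int
    successes: int
    total: int
    p0: float
    proportion: float
    p_value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ExclusionReport:
    trials_excluded_one_bin: int
    participants_excluded_constant_estimate: int
    participants_excluded_two_rounds: int
    retained_participants: int


def apply_exclusions(records) -> tuple[list, ExclusionReport]:
    """Apply the preregistered exclusion rules.

    1. Trials in which only one bin was sampled are dropped.
    2. Participants whose estimate is identical on all their trials are dropped.
    3. Participants with two or more dropped trials are dropped entirely.

    Returns the retained trials (original order) and a tally report.
    """
    if not records:
        return [], ExclusionReport(0, 0, 0, 0)

    by_participant: "OrderedDict[str, list]" = OrderedDict()
    for r in records:
        by_participant.setdefault(r.participant_id, []).append(r)

    n_one_bin = 0
    n_constant = 0
    n_two_rounds = 0
    kept: list = []
    for pid, trials in by_participant.items():
        flagged = [int(np.count_nonzero(t.counts)) == 1 for t in trials]
        n_one_bin += sum(flagged)
        estimates = [t.estimate_raw for t in trials]
        if len(trials) > 1 and all(e == estimates[0] for e in estimates):
            n_constant += 1
            continue
        if sum(flagged) >= 2:
            n_two_rounds += 1
            continue
        kept.extend(t for t, bad in zip(trials, flagged) if not bad)

    retained = len({t.participant_id for t in kept})
    report = ExclusionReport(
        trials_excluded_one_bin=n_one_bin,
        participants_excluded_constant_estimate=n_constant,
        participants_excluded_two_rounds=n_two_rounds,
        retained_participants=retained,
    )
    return kept, report


def experienced_mean(trial) -> float:
    """Arithmetic mean of the trial's normalized drawn values."""
    if len(trial.draw_values) == 0:
        raise ValueError("experienced mean is undefined for a trial with no draws")
    return float(np.mean(trial.draw_values))


def trial_statistics(trial, dist: BinnedDistribution | None = None) -> TrialStatistics:
    """Sampling bias, estimation deviation and adjustment for one trial.

    The true mean depends only on the shape condition on the normalized scale,
    so ``dist`` may be omitted.
    """
    if dist is not None:
        mu = dist.mu
    else:
        mu = ShapeCondition.from_label(trial.condition).mean
    exp_mean = experienced_mean(trial)
    est = trial.estimate_raw / trial.multiplier
    return TrialStatistics(
        sampling_bias=exp_mean - mu,
        estimation_deviation=est - mu,
        estimation_adjustment=exp_mean - est,
    )


def pooled_bin_test(records, condition: str, bin_index: int, p0: float) -> ProportionTest:
    """Exact two-sided binomial test of the pooled share of samples in one bin.

    All samples across trials and participants in ``condition`` are pooled.
    The two-sided p-value doubles the smaller tail (capped at 1); the interval
    is the Clopper–Pearson exact 95% CI.  ``bin_index`` is 1-based.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"null probability p0 must lie in (0, 1), got {p0}")
    subset = [r for r in records if r.condition == condition]
    if not subset:
        raise ValueError(f"no records in condition {condition!r}")
    successes = int(sum(int(r.counts[bin_index - 1]) for r in subset))
    total = int(sum(int(np.sum(r.counts)) for r in subset))
    if total == 0:
        raise ValueError("zero pooled samples")

    lower_tail = stats.binom.cdf(successes, total, p0)
    upper_tail = stats.binom.sf(successes - 1, total, p0)
    p_value = min(1.0, 2.0 * min(lower_tail, upper_tail))

    ci = stats.binomtest(successes, total, p0).proportion_ci(
        confidence_level=0.95, method="exact"
    )
    return ProportionTest(
        bin_index=bin_index,
        successes=successes,
        total=total,
        p0=p0,
        proportion=successes / total,
        p_value=float(p_value),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def _cluster_bootstrap_ci(
    values_by_participant: list[np.ndarray],
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile CI of the trial-level mean, resampling participants."""
    P = len(values_by_participant)
    boot = np.empty((n_boot, values_by_participant[0].shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, P, size=P)
        stacked = np.concatenate([values_by_participant[i] for i in idx], axis=0)
        boot[b] = stacked.mean(axis=0)
    return np.percentile(boot, 2.5, axis=0), np.percentile(boot, 97.5, axis=0)


def condition_summaries(
    records,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> list[BiasSummary]:
    """Per condition × budget means with participant-clustered bootstrap 95% CIs.

    Trials are the unit of averaging; the bootstrap resamples participants with
    replacement within each cell (``n_boot`` replicates).  Cells with no trials
    are omitted with a warning.
    """
    rng = rng or np.random.default_rng(0)
    cells: "OrderedDict[tuple[str, int], OrderedDict[str, list]]" = OrderedDict()
    for r in records:
        cell = cells.setdefault((r.condition, r.budget), OrderedDict())
        cell.setdefault(r.participant_id, []).append(r)

    summaries: list[BiasSummary] = []
    for (condition, budget), by_pid in sorted(cells.items()):
        per_participant = []
        for trials in by_pid.values():
            ts = [trial_statistics(t) for t in trials]
            per_participant.append(
                np.array(
                    [
                        [s.sampling_bias, s.estimation_deviation, s.estimation_adjustment]
                        for s in ts
                    ]
                )
            )
        stacked = np.concatenate(per_participant, axis=0)
        if stacked.shape[0] == 0:
            logger.warning("condition %s × budget %d has no trials; omitted", condition, budget)
            continue
        means = stacked.mean(axis=0)
        lo, hi = _cluster_bootstrap_ci(per_participant, n_boot, rng)
        summaries.append(
            BiasSummary(
                condition=condition,
                budget=budget,
                mean_sampling_bias=float(means[0]),
                mean_estimation_deviation=float(means[1]),
                mean_estimation_adjustment=float(means[2]),
                ci_sampling_bias=(float(lo[0]), float(hi[0])),
                ci_estimation_deviation=(float(lo[1]), float(hi[1])),
                ci_estimation_adjustment=(float(lo[2]), float(hi[2])),
                n_trials=int(stacked.shape[0]),
            )
        )
    return summaries


@dataclass(frozen=True)
class StratifiedEfficiency:
    var_stratified: float
    var_srs: float
    variance_ratio: float


def stratified_efficiency(dist: BinnedDistribution, budget: int) -> StratifiedEfficiency:
    """Variance of the mean estimator under proportional stratified vs. simple random sampling.

    var_stratified = (1/N) · sum_k g_k s2_k   (within-bin variance only),
    var_srs        = Var(X)/N, with the decomposition
    Var(X) = sum_k g_k s2_k + sum_k g_k (m_k − mu)^2, hence ratio ≤ 1.
    """
    if budget < 1:
        raise ValueError(f"budget must be >= 1, got {budget}")
    within = float(dist.g @ dist.s2)
    total = within + float(dist.g @ (dist.m - dist.mu) ** 2)
    var_strat = within / budget
    var_srs = total / budget
    return StratifiedEfficiency(var_strat, var_srs, var_strat / var_srs)


def payoff_loss(mean_abs_deviation: float, max_bonus: float = 8.0) -> float:
    """Expected incentive loss under a linear payoff rule: deviation × bonus."""
    if not 0.0 <= mean_abs_deviation <= 1.0:
        raise ValueError("mean absolute deviation must lie in [0, 1]")
    if max_bonus < 0.0:
        raise ValueError("max_bonus must be >= 0")
    return mean_abs_deviation * max_bonus
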