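"""Binned, scaled beta stimulus distributions for the star-rating sampling task.

The task environment shows a five-bin histogram of "star ratings" whose bin
probabilities come from one of three beta distributions on [0, 1]:

* negatively skewed  Beta(3, 1)   — rare low outcomes,
* positively skewed  Beta(1, 3)   — rare high outcomes,
* uniform            Beta(1, 1)   — flat baseline.

Clicking a bin draws a "positivity score" from the beta distribution restricted
to that bin's interval, scaled by a per-trial multiplier drawn uniformly from
[50, 100] so that the raw range is hidden from the sampler.  All statistics in
this package are computed on the normalized [0, 1] scale; the multiplier is
applied only when producing raw positivity scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ShapeCondition",
    "BinnedDistribution",
    "NEGATIVE",
    "POSITIVE",
    "UNIFORM",
    "CONDITIONS",
    "CONDITION_LABELS",
    "bin_probabilities",
    "bin_conditional_moments",
    "true_mean",
    "bin_quantile",
    "draw_from_bin",
    "make_trial_stimulus",
]

#: the only constructible (alpha, beta) pairs, keyed by condition label
_SHAPES: dict[str, tuple[float, float]] = {
    "negative": (3.0, 1.0),
    "positive": (1.0, 3.0),
    "uniform": (1.0, 1.0),
}

MULTIPLIER_LOW = 50.0
MULTIPLIER_HIGH = 100.0
DEFAULT_N_BINS = 5


@dataclass(frozen=True)
class ShapeCondition:
    """One of the three histogram shape conditions.

    Only the pairs Beta(3,1) ("negative"), Beta(1,3) ("positive") and
    Beta(1,1) ("uniform") are constructible; use :meth:`from_label` or the
    module constants :data:`NEGATIVE`, :data:`POSITIVE`, :data:`UNIFORM`.
    """

    label: str
    alpha: float
    beta_param: float

    def __post_init__(self) -> None:
        if self.label not in _SHAPES:
            raise ValueError(
                f"unknown shape condition {self.label!r}; "
                f"expected one of {sorted(_SHAPES)}"
            )
        expected = _SHAPES[self.label]
        if (self.alpha, self.beta_param) != expected:
            raise ValueError(
                f"condition {self.label!r} must have (alpha, beta) = {expected}, "
                f"got {(self.alpha, self.beta_param)}"
            )

    @classmethod
    def from_label(cls, label: str) -> "ShapeCondition":
        if label not in _SHAPES:
            raise ValueError(
                f"unknown shape condition {label!r}; expected one of {sorted(_SHAPES)}"
            )
        a, b = _SHAPES[label]
        return cls(label, a, b)

    @property
    def mean(self) -> float:
        """True mean alpha/(alpha+beta) on the normalized scale."""
        return self.alpha / (self.alpha + self.beta_param)

    @property
    def variance(self) -> float:
        """Total variance of the beta distribution on the normalized scale."""
        a, b = self.alpha, self.beta_param
        return a * b / ((a + b) ** 2 * (a + b + 1.0))

    def cdf(self, x) -> np.ndarray:
        return stats.beta.cdf(x, self.alpha, self.beta_param)

    def ppf(self, q) -> np.ndarray:
        return stats.beta.ppf(q, self.alpha, self.beta_param)


NEGATIVE = ShapeCondition.from_label("negative")
POSITIVE = ShapeCondition.from_label("positive")
UNIFORM = ShapeCondition.from_label("uniform")
CONDITIONS: tuple[ShapeCondition, ...] = (NEGATIVE, POSITIVE, UNIFORM)
CONDITION_LABELS: tuple[str, ...] = tuple(c.label for c in CONDITIONS)


def _bin_edges(n_bins: int) -> np.ndarray:
    if not isinstance(n_bins, (int, np.integer)) or n_bins < 2:
        raise ValueError(f"n_bins must be an integer >= 2, got {n_bins!r}")
    return np.linspace(0.0, 1.0, n_bins + 1)


def bin_probabilities(condition: ShapeCondition, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Exact probability mass of each equal-width bin under the beta CDF.

    Returns a length-``n_bins`` vector ``g`` with ``g[k] = F(b_k) - F(a_k)``.
    """
    edges = _bin_edges(n_bins)
    g = np.diff(condition.cdf(edges))
    return g


def _partial_moment(condition: ShapeCondition, lo: float, hi: float, order: int) -> float:
    """E[X^order · 1{lo < X < hi}] for X ~ Beta(alpha, beta).

    Uses the shift identity E[X^r 1{A}] = c_r · P_{alpha+r, beta}(A) with
    c_r = prod_{j<r} (alpha+j)/(alpha+beta+j).
    """
    a, b = condition.alpha, condition.beta_param
    coef = 1.0
    for j in range(order):
        coef *= (a + j) / (a + b + j)
    return coef * float(
        stats.beta.cdf(hi, a + order, b) - stats.beta.cdf(lo, a + order, b)
    )


def bin_conditional_moments(
    condition: ShapeCondition, k: int, n_bins: int = DEFAULT_N_BINS
) -> tuple[float, float]:
    """Exact mean and variance of the beta distribution restricted to bin ``k``.

    ``k`` is 1-based (bin 1 is the lowest interval).  Both moments are on the
    normalized [0, 1] scale.
    """
    edges = _bin_edges(n_bins)
    if not 1 <= k <= n_bins:
        raise IndexError(f"bin index {k} out of range 1..{n_bins}")
    lo, hi = edges[k - 1], edges[k]
    mass = float(condition.cdf(hi) - condition.cdf(lo))
    m1 = _partial_moment(condition, lo, hi, 1) / mass
    m2 = _partial_moment(condition, lo, hi, 2) / mass
    return m1, m2 - m1 * m1


@dataclass(frozen=True)
class BinnedDistribution:
    """A trial's stimulus: a binned beta distribution with a hidden scale.

    All derived fields (``g``, ``m``, ``s2``, ``mu``) are on the normalized
    [0, 1] scale; ``multiplier`` converts to raw positivity-score units.
    """

    condition: ShapeCondition
    multiplier: float
    n_bins: int = DEFAULT_N_BINS
    edges: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    g: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    m: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    s2: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    mu: float = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (MULTIPLIER_LOW <= self.multiplier <= MULTIPLIER_HIGH):
            raise ValueError(
                f"multiplier must lie in [{MULTIPLIER_LOW}, {MULTIPLIER_HIGH}], "
                f"got {self.multiplier}"
            )
        edges = _bin_edges(self.n_bins)
        g = bin_probabilities(self.condition, self.n_bins)
        moments = [
            bin_conditional_moments(self.condition, k, self.n_bins)
            for k in range(1, self.n_bins + 1)
        ]
        m = np.array([mo[0] for mo in moments])
        s2 = np.array([mo[1] for mo in moments])
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "s2", s2)
        object.__setattr__(self, "mu", self.condition.mean)

    @classmethod
    def from_condition(
        cls,
        condition: ShapeCondition,
        multiplier: float,
        n_bins: int = DEFAULT_N_BINS,
    ) -> "BinnedDistribution":
        return cls(condition=condition, multiplier=multiplier, n_bins=n_bins)


def true_mean(dist: BinnedDistribution, normalized: bool = True) -> float:
    """True mean of the stimulus, normalized or in raw positivity-score units."""
    mu = dist.mu
    return mu if normalized else mu * dist.multiplier


def bin_quantile(
    dist: BinnedDistribution, k: int, u, normalized: bool = False
) -> np.ndarray | float:
    """Quantile ``u`` of the beta distribution truncated to bin ``k`` (1-based).

    Inverts the bin-truncated CDF: ``x = F^{-1}(F(a_k) + u · (F(b_k) − F(a_k)))``.
    Raw scale unless ``normalized``.
    """
    if not 1 <= k <= dist.n_bins:
        raise IndexError(f"bin index {k} out of range 1..{dist.n_bins}")
    cond = dist.condition
    lo, hi = dist.edges[k - 1], dist.edges[k]
    flo, fhi = cond.cdf(lo), cond.cdf(hi)
    x = cond.ppf(flo + np.asarray(u) * (fhi - flo))
    if not normalized:
        x = x * dist.multiplier
    if np.ndim(u) == 0:
        return float(x)
    return x


def draw_from_bin(
    dist: BinnedDistribution,
    k: int,
    rng: np.random.Generator,
    size: int | None = None,
    normalized: bool = False,
):
    """Sample positivity scores from bin ``k`` by inverse-CDF of the truncated beta."""
    u = rng.random() if size is None else rng.random(size)
    return bin_quantile(dist, k, u, normalized=normalized)


def make_trial_stimulus(
    condition: ShapeCondition,
    rng: np.random.Generator,
    n_bins: int = DEFAULT_N_BINS,
) -> BinnedDistribution:
    """Create one trial's stimulus with a multiplier drawn from Uniform(50, 100)."""
    multiplier = rng.uniform(MULTIPLIER_LOW, MULTIPLIER_HIGH)
    return BinnedDistribution.from_condition(condition, multiplier, n_bins)
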