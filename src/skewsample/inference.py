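"""Hierarchical Bayesian inference of the cognitive-fencing mixture weight.

Model.  Each participant i allocates trial budgets over the five bins with
probabilities f_k(w_i) = (1−w_i)·g_k + w_i/5, observed as multinomial counts.
Only the two skewed conditions enter the likelihood: in the uniform condition
f(w) = g for every w, so those trials carry no information about w.  The
participant weights share a truncated-normal population prior,

    counts_it ~ Multinomial(N_it, f(w_i)),
    w_i       ~ Normal(mu_w, sigma_w) truncated to [0, 1],
    mu_w      ~ Normal(0.5, 1) truncated to [0, 1],
    sigma_w   ~ Half-Normal(1).

Sampling.  An adaptive random-walk Metropolis-within-Gibbs sampler on
transformed parameters (logit w_i, logit mu_w, log sigma_w): the P weight
components are conditionally independent given the hyperparameters and are
updated in a single vectorized step; the two hyperparameters get scalar
updates.  Proposal scales adapt toward a 44% acceptance rate during warmup
(diminishing-adaptation batches).  Convergence is monitored with the
rank-normalized potential scale reduction factor (R-hat) and effective sample
size via ArviZ; R-hat above 1.05 on a hyperparameter raises a warning and
flags the fit as non-converged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit, ndtr

from .agents import ExperimentDesign, PopulationParams, mixture_probs, simulate_experiment
from .biasstats import trial_statistics
from .stimuli import NEGATIVE, POSITIVE, bin_probabilities

__all__ = [
    "MCMCConfig",
    "PosteriorSummary",
    "ConvergenceWarning",
    "allocation_loglik",
    "log_posterior",
    "prepare_skewed_counts",
    "fit_hierarchical",
    "recovery_study",
    "adjustment_regression",
]

SKEWED_LABELS = ("negative", "positive")
_SQRT_2PI = np.sqrt(2.0 * np.pi)


class ConvergenceWarning(UserWarning):
    """Raised when MCMC diagnostics exceed their thresholds."""


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 4
    n_iterations: int = 2000  # per chain, including warmup
    n_warmup: int = 1000
    seed: int = 0
    initial_step_w: float = 0.5
    initial_step_hyper: float = 0.3

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if not 0 < self.n_warmup < self.n_iterations:
            raise ValueError("need 0 < n_warmup < n_iterations")
        if self.initial_step_w <= 0 or self.initial_step_hyper <= 0:
            raise ValueError("proposal scales must be positive")


@dataclass
class PosteriorSummary:
    """Posterior draws and summaries for mu_w, sigma_w and per-participant w."""

    participant_ids: list[str]
    draws: dict[str, np.ndarray]  # "mu_w"/"sigma_w": (chains, draws); "w": (chains, draws, P)
    posterior_mean: dict[str, np.ndarray | float]
    ci95: dict[str, np.ndarray | tuple[float, float]]
    rhat: dict[str, float | np.ndarray]
    ess: dict[str, float | np.ndarray]
    converged: bool

    @property
    def w_means(self) -> dict[str, float]:
        """Posterior mean of w keyed by participant id."""
        means = np.asarray(self.posterior_mean["w"])
        return {pid: float(m) for pid, m in zip(self.participant_ids, means)}


# ---------------------------------------------------------------------------
# densities


def _truncnorm01_logpdf(x, mu, sigma) -> np.ndarray:
    """Log density of Normal(mu, sigma) truncated to [0, 1], vectorized."""
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    norm = ndtr((1.0 - mu) / sigma) - ndtr((0.0 - mu) / sigma)
    out = -0.5 * z * z - np.log(sigma * _SQRT_2PI) - np.log(norm)
    return np.where((x >= 0.0) & (x <= 1.0), out, -np.inf)


def _log_hyperprior(mu_w: float, sigma_w: float) -> float:
    """Weak hyperpriors: mu_w ~ TruncNormal(0.5, 1, [0,1]); sigma_w ~ Half-Normal(1)."""
    if sigma_w <= 0.0 or not 0.0 <= mu_w <= 1.0:
        return -np.inf
    lp_mu = float(_truncnorm01_logpdf(mu_w, 0.5, 1.0))
    lp_sigma = 0.5 * np.log(2.0 / np.pi) - 0.5 * sigma_w * sigma_w
    return lp_mu + lp_sigma


def allocation_loglik(counts, g, w: float) -> float:
    """Multinomial log-likelihood of a counts vector under the mixture policy.

    Includes the multinomial coefficient.  −inf iff a bin with zero mixture
    probability received a positive count (possible only at w = 0 when g has
    a zero entry).
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = int(counts.sum())
    if n < 1:
        raise ValueError("counts must sum to at least 1")
    f = mixture_probs(np.asarray(g, dtype=float), w)
    coef = gammaln(n + 1) - gammaln(counts + 1).sum()
    with np.errstate(divide="ignore"):
        logf = np.log(f)
    terms = np.where(counts > 0, counts * logf, 0.0)
    return float(coef + terms.sum())


def log_posterior(counts_by_participant, w, mu_w: float, sigma_w: float) -> float:
    """Joint log posterior of the hierarchical model (up to nothing: all terms included).

    ``counts_by_participant`` is a sequence over participants; each element is
    a sequence of ``(counts, g)`` pairs, one per skewed-condition trial.
    """
    if sigma_w <= 0.0:
        return -np.inf
    w = np.asarray(w, dtype=float)
    if np.any((w < 0.0) | (w > 1.0)):
        return -np.inf
    total = _log_hyperprior(mu_w, sigma_w)
    total += float(np.sum(_truncnorm01_logpdf(w, mu_w, sigma_w)))
    for wi, trials in zip(w, counts_by_participant):
        for counts, g in trials:
            total += allocation_loglik(counts, g, float(wi))
    return float(total)


# ---------------------------------------------------------------------------
# data preparation


def prepare_skewed_counts(records) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pool each participant's skewed-condition counts into a (P, 2, 5) array.

    Pooling trials within a condition is lossless for the likelihood because
    the mixture probabilities are identical across trials of one condition.
    Returns (participant ids, counts array, g matrix with rows negative/positive).
    """
    skewed = [r for r in records if r.condition in SKEWED_LABELS]
    if not skewed:
        raise ValueError("no informative (skewed-condition) trials in the data")
    ids: list[str] = []
    index: dict[str, int] = {}
    for r in skewed:
        if r.participant_id not in index:
            index[r.participant_id] = len(ids)
            ids.append(r.participant_id)
    n_bins = len(skewed[0].counts)
    C = np.zeros((len(ids), 2, n_bins))
    for r in skewed:
        C[index[r.participant_id], SKEWED_LABELS.index(r.condition)] += np.asarray(r.counts)
    G = np.vstack(
        [bin_probabilities(NEGATIVE, n_bins), bin_probabilities(POSITIVE, n_bins)]
    )
    return ids, C, G


def _loglik_all(C: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-participant log-likelihood (without multinomial constants)."""
    f = (1.0 - w)[:, None, None] * G[None, :, :] + w[:, None, None] / G.shape[1]
    return np.einsum("pck,pck->p", C, np.log(f))


# ---------------------------------------------------------------------------
# sampler


def _run_chain(
    C: np.ndarray,
    G: np.ndarray,
    config: MCMCConfig,
    seed: np.random.SeedSequence,
    fixed_hypers: tuple[float, float] | None,
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    P = C.shape[0]
    n_keep = config.n_iterations - config.n_warmup

    zeta = rng.normal(0.0, 1.0, size=P)
    w = expit(zeta)
    if fixed_hypers is not None:
        mu_w, sigma_w = fixed_hypers
        eta = lam = 0.0
    else:
        mu_w = float(rng.uniform(0.3, 0.7))
        sigma_w = float(rng.uniform(0.1, 0.5))
        eta = float(logit(mu_w))
        lam = float(np.log(sigma_w))

    step_w = np.full(P, config.initial_step_w)
    step_eta = step_lam = config.initial_step_hyper

    ll = _loglik_all(C, G, w)
    tn_w = _truncnorm01_logpdf(w, mu_w, sigma_w)
    jac_w = np.log(w) + np.log1p(-w)

    def hyper_logdens(mu: float, sigma: float, tn_sum: float) -> float:
        # log p(w | mu, sigma) + hyperpriors + transform jacobians (constants dropped)
        return (
            tn_sum
            - 0.5 * (mu - 0.5) ** 2  # Normal(0.5, 1) kernel
            - 0.5 * sigma * sigma
            + np.log(mu)
            + np.log1p(-mu)
            + np.log(sigma)
        )

    out_w = np.empty((n_keep, P))
    out_mu = np.empty(n_keep)
    out_sigma = np.empty(n_keep)

    acc_w = np.zeros(P)
    acc_eta = acc_lam = 0.0
    batch = 0
    ADAPT_EVERY = 50
    TARGET = 0.44

    for it in range(config.n_iterations):
        # --- vectorized per-participant w update ---------------------------
        zeta_prop = zeta + step_w * rng.standard_normal(P)
        w_prop = expit(zeta_prop)
        ll_prop = _loglik_all(C, G, w_prop)
        tn_prop = _truncnorm01_logpdf(w_prop, mu_w, sigma_w)
        jac_prop = np.log(w_prop) + np.log1p(-w_prop)
        log_alpha = (ll_prop + tn_prop + jac_prop) - (ll + tn_w + jac_w)
        accept = np.log(rng.random(P)) < log_alpha
        zeta = np.where(accept, zeta_prop, zeta)
        w = np.where(accept, w_prop, w)
        ll = np.where(accept, ll_prop, ll)
        tn_w = np.where(accept, tn_prop, tn_w)
        jac_w = np.where(accept, jac_prop, jac_w)
        acc_w += accept

        if fixed_hypers is None:
            # --- mu_w update -----------------------------------------------
            eta_prop = eta + step_eta * rng.standard_normal()
            mu_prop = float(expit(eta_prop))
            tn_at_prop = _truncnorm01_logpdf(w, mu_prop, sigma_w)
            la = hyper_logdens(mu_prop, sigma_w, float(tn_at_prop.sum())) - hyper_logdens(
                mu_w, sigma_w, float(tn_w.sum())
            )
            if np.log(rng.random()) < la:
                eta, mu_w, tn_w = eta_prop, mu_prop, tn_at_prop
                acc_eta += 1.0

            # --- sigma_w update --------------------------------------------
            lam_prop = lam + step_lam * rng.standard_normal()
            sigma_prop = float(np.exp(lam_prop))
            tn_at_prop = _truncnorm01_logpdf(w, mu_w, sigma_prop)
            la = hyper_logdens(mu_w, sigma_prop, float(tn_at_prop.sum())) - hyper_logdens(
                mu_w, sigma_w, float(tn_w.sum())
            )
            if np.log(rng.random()) < la:
                lam, sigma_w, tn_w = lam_prop, sigma_prop, tn_at_prop
                acc_lam += 1.0

        # --- warmup adaptation ---------------------------------------------
        if it < config.n_warmup and (it + 1) % ADAPT_EVERY == 0:
            batch += 1
            delta = min(0.25, 1.0 / np.sqrt(batch))
            step_w *= np.exp(np.where(acc_w / ADAPT_EVERY > TARGET, delta, -delta))
            if fixed_hypers is None:
                step_eta *= np.exp(delta if acc_eta / ADAPT_EVERY > TARGET else -delta)
                step_lam *= np.exp(delta if acc_lam / ADAPT_EVERY > TARGET else -delta)
            acc_w[:] = 0.0
            acc_eta = acc_lam = 0.0

        if it >= config.n_warmup:
            j = it - config.n_warmup
            out_w[j] = w
            out_mu[j] = mu_w
            out_sigma[j] = sigma_w

    return {"w": out_w, "mu_w": out_mu, "sigma_w": out_sigma}


def fit_hierarchical(
    records,
    config: MCMCConfig | None = None,
    fixed_hypers: tuple[float, float] | None = None,
) -> PosteriorSummary:
    """Fit the hierarchical mixture-weight model to trial records by MCMC.

    ``records`` should already have passed exclusions; only skewed-condition
    trials enter the likelihood.  With ``fixed_hypers=(mu_w, sigma_w)`` the
    hyperparameters are held fixed and only the participant weights are
    sampled (useful for single-participant checks).  Reproducible from
    ``config.seed``.
    """
    config = config or MCMCConfig()
    ids, C, G = prepare_skewed_counts(records)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [_run_chain(C, G, config, s, fixed_hypers) for s in seeds]

    draws = {
        "mu_w": np.stack([c["mu_w"] for c in chains]),
        "sigma_w": np.stack([c["sigma_w"] for c in chains]),
        "w": np.stack([c["w"] for c in chains]),
    }

    idata = az.from_dict(posterior=draws)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant chains under fixed hypers
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat = {
        "mu_w": float(rhat_ds["mu_w"].values),
        "sigma_w": float(rhat_ds["sigma_w"].values),
        "w": np.asarray(rhat_ds["w"].values),
    }
    ess = {
        "mu_w": float(ess_ds["mu_w"].values),
        "sigma_w": float(ess_ds["sigma_w"].values),
        "w": np.asarray(ess_ds["w"].values),
    }

    if fixed_hypers is None:
        converged = rhat["mu_w"] <= 1.05 and rhat["sigma_w"] <= 1.05
    else:
        converged = bool(np.nanmax(rhat["w"]) <= 1.05)
    if not converged:
        warnings.warn(
            "MCMC did not reach R-hat <= 1.05 on the hyperparameters; "
            "increase n_iterations or inspect the data",
            ConvergenceWarning,
            stacklevel=2,
        )

    def summarize(x: np.ndarray, axis=(0, 1)):
        mean = x.mean(axis=axis)
        lo = np.percentile(x, 2.5, axis=axis)
        hi = np.percentile(x, 97.5, axis=axis)
        return mean, lo, hi

    mu_mean, mu_lo, mu_hi = summarize(draws["mu_w"])
    sg_mean, sg_lo, sg_hi = summarize(draws["sigma_w"])
    w_mean, w_lo, w_hi = summarize(draws["w"])

    return PosteriorSummary(
        participant_ids=ids,
        draws=draws,
        posterior_mean={
            "mu_w": float(mu_mean),
            "sigma_w": float(sg_mean),
            "w": np.asarray(w_mean),
        },
        ci95={
            "mu_w": (float(mu_lo), float(mu_hi)),
            "sigma_w": (float(sg_lo), float(sg_hi)),
            "w": np.vstack([w_lo, w_hi]),
        },
        rhat=rhat,
        ess=ess,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# recovery harness and follow-up regression


def recovery_study(
    grid,
    design: ExperimentDesign | None = None,
    n_replications: int = 10,
    seed: int = 0,
    config: MCMCConfig | None = None,
    kappa: float | None = None,
    sigma_e: float | None = None,
) -> pd.DataFrame:
    """Parameter-recovery table over a grid of (mu_w, sigma_w) population cells.

    For each cell, ``n_replications`` experiments are simulated and fitted;
    the table reports the bias and RMSE of the posterior-mean hyperparameters
    and the coverage of their 95% credible intervals.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    base_design = design or ExperimentDesign()
    config = config or MCMCConfig()
    from .agents import DEFAULT_KAPPA, DEFAULT_SIGMA_E

    kappa = DEFAULT_KAPPA if kappa is None else kappa
    sigma_e = DEFAULT_SIGMA_E if sigma_e is None else sigma_e

    root = np.random.SeedSequence(seed)
    rows = []
    for mu_true, sigma_true in grid:
        cell_seeds = root.spawn(n_replications)
        est_mu, est_sigma, cover_mu, cover_sigma = [], [], [], []
        for ss in cell_seeds:
            sim_seed, fit_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
            d = ExperimentDesign(
                n_participants=base_design.n_participants,
                budget_split=base_design.budget_split,
                trials_per_condition=base_design.trials_per_condition,
                seed=sim_seed,
            )
            records = simulate_experiment(
                d, PopulationParams(mu_true, sigma_true), kappa=kappa, sigma_e=sigma_e
            )
            cfg = MCMCConfig(
                n_chains=config.n_chains,
                n_iterations=config.n_iterations,
                n_warmup=config.n_warmup,
                seed=fit_seed,
            )
            post = fit_hierarchical(records, cfg)
            est_mu.append(post.posterior_mean["mu_w"])
            est_sigma.append(post.posterior_mean["sigma_w"])
            lo, hi = post.ci95["mu_w"]
            cover_mu.append(lo <= mu_true <= hi)
            lo, hi = post.ci95["sigma_w"]
            cover_sigma.append(lo <= sigma_true <= hi)
        est_mu = np.array(est_mu)
        est_sigma = np.array(est_sigma)
        rows.append(
            {
                "mu_w_true": mu_true,
                "sigma_w_true": sigma_true,
                "bias_mu_w": float(est_mu.mean() - mu_true),
                "rmse_mu_w": float(np.sqrt(np.mean((est_mu - mu_true) ** 2))),
                "coverage_mu_w": float(np.mean(cover_mu)),
                "bias_sigma_w": float(est_sigma.mean() - sigma_true),
                "rmse_sigma_w": float(np.sqrt(np.mean((est_sigma - sigma_true) ** 2))),
                "coverage_sigma_w": float(np.mean(cover_sigma)),
                "n_replications": n_replications,
            }
        )
    return pd.DataFrame(rows)


def adjustment_regression(
    records,
    w_means: dict[str, float],
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Regress absolute estimation adjustment on w, condition, and interaction.

    Linear model |adjustment| ~ w * condition with participant-clustered
    percentile-bootstrap 95% intervals (``n_boot`` resamples of participants).
    With a single condition in the data the condition terms are dropped with a
    warning.  Returns a coefficient table with an ``excludes_zero`` flag.
    """
    import statsmodels.formula.api as smf

    rng = rng or np.random.default_rng(0)
    rows = []
    for r in records:
        if r.participant_id not in w_means:
            continue
        stats_r = trial_statistics(r)
        rows.append(
            {
                "participant_id": r.participant_id,
                "abs_adjustment": abs(stats_r.estimation_adjustment),
                "w": w_means[r.participant_id],
                "condition": r.condition,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no records with fitted w values")

    n_conditions = df["condition"].nunique()
    if n_conditions >= 2:
        formula = "abs_adjustment ~ w * C(condition)"
    else:
        warnings.warn(
            "single condition in data: fitting reduced model without condition terms",
            UserWarning,
            stacklevel=2,
        )
        formula = "abs_adjustment ~ w"
    model = smf.ols(formula, data=df)
    fit = model.fit()
    X = model.exog
    y = model.endog
    names = list(model.exog_names)

    pids = df["participant_id"].to_numpy()
    unique_pids = pd.unique(pids)
    row_idx = {pid: np.flatnonzero(pids == pid) for pid in unique_pids}
    P = len(unique_pids)

    boot = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        sampled = rng.integers(0, P, size=P)
        take = np.concatenate([row_idx[unique_pids[i]] for i in sampled])
        coef, *_ = np.linalg.lstsq(X[take], y[take], rcond=None)
        boot[b] = coef

    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    return pd.DataFrame(
        {
            "term": names,
            "estimate": fit.params.to_numpy(),
            "ci_low": lo,
            "ci_high": hi,
            "excludes_zero": (lo > 0) | (hi < 0),
        }
    )
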