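"""Bayesian observer models of probability estimation from sampled evidence.

An observer infers the unknown proportion of blue marbles in a jar from five
successive binomial samples. Belief over the proportion is a beta distribution,
updated conjugately after each sample; model variants differ in

* the symmetric prior width ``rho`` (alpha = beta = rho; rho = 1 is flat,
  larger rho concentrates prior belief on 0.5),
* an evidence-weight exponent ``delta`` applied to the per-sample blue/red
  counts before updating (delta < 1 underweights large samples), and
* the response rule: either a truncated-normal report centered on the
  posterior mean with noise ``sigma``, or a random draw from the final beta
  distribution snapped to the 1/100 response grid.

A Rescorla-Wagner point-estimate learner (delta rule with free learning rate,
truncated-normal response noise) serves as the non-Bayesian comparison model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "FAMILIES",
    "BAYES_FAMILIES",
    "SIGMA_FAMILIES",
    "DRAW_FAMILIES",
    "BeliefState",
    "ObserverSpec",
    "SampleDraw",
    "TrialRecord",
    "init_belief",
    "update_belief",
    "belief_moments",
    "trial_trajectory",
    "posterior_sd_trajectory",
    "rw_trajectory",
    "predicted_estimate",
    "response_loglik",
    "dataset_negloglik",
    "response_grid",
]

SIGMA_FAMILIES = ("bayes_rho_sigma", "bayes_delta_sigma", "rescorla_wagner")
DRAW_FAMILIES = ("bayes_rho_draw", "bayes_delta_draw")
BAYES_FAMILIES = (
    "bayes_rho_sigma",
    "bayes_delta_sigma",
    "bayes_rho_draw",
    "bayes_delta_draw",
)
FAMILIES = BAYES_FAMILIES + ("rescorla_wagner",)

#: free parameters per model family, in canonical order
FAMILY_PARAMS = {
    "bayes_rho_sigma": ("rho", "sigma"),
    "bayes_delta_sigma": ("delta", "sigma"),
    "bayes_rho_draw": ("rho",),
    "bayes_delta_draw": ("delta",),
    "rescorla_wagner": ("learning_rate", "sigma"),
}

#: reported estimates live on this grid (a 100-marble response grid)
GRID_STEP = 0.01


@dataclass(frozen=True)
class SampleDraw:
    """One sample of marbles: ``n_blue`` blue and ``n_red`` red."""

    n_blue: int
    n_red: int

    def __post_init__(self) -> None:
        if self.n_blue < 0 or self.n_red < 0:
            raise ValueError("marble counts must be non-negative")

    @property
    def size(self) -> int:
        return self.n_blue + self.n_red

    @property
    def proportion_blue(self) -> float:
        if self.size == 0:
            return math.nan
        return self.n_blue / self.size


@dataclass(frozen=True)
class BeliefState:
    """Beta-distributed belief over the blue-marble proportion.

    The variance of the belief is the observer's uncertainty about the
    latent state; it is bounded by ``1 / (4 (alpha + beta + 1))``.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("beta-distribution parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class ObserverSpec:
    """A model family together with its parameter values."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if "rho" in self.params and self.params["rho"] < 1:
            raise ValueError("rho must be >= 1")
        if "delta" in self.params and self.params["delta"] < 0:
            raise ValueError("delta must be >= 0")
        if "sigma" in self.params and self.params["sigma"] <= 0:
            raise ValueError("sigma must be > 0")
        if "learning_rate" in self.params and not (
            0.0 <= self.params["learning_rate"] <= 1.0
        ):
            raise ValueError("learning_rate must lie in [0, 1]")

    @property
    def n_params(self) -> int:
        return len(FAMILY_PARAMS[self.family])

    @property
    def rho(self) -> float:
        return float(self.params.get("rho", 1.0))

    @property
    def delta(self) -> float:
        return float(self.params.get("delta", 1.0))


@dataclass
class TrialRecord:
    """One trial: five sample draws plus the subject's reported estimate.

    ``reported_estimate`` is NaN for missing responses (trial excluded from
    fitting and error computation upstream).
    """

    draws: list
    reported_estimate: float = math.nan
    jar_p_blue: float = math.nan
    trial_id: int = -1

    @property
    def valid(self) -> bool:
        return not math.isnan(self.reported_estimate)

    def experienced_proportion(self, method: str = "pooled") -> float:
        """Proportion of blue marbles actually observed on this trial.

        ``pooled`` (default) divides total blue by total marbles; ``mean``
        averages the per-sample proportions instead.
        """
        if method == "pooled":
            blue = sum(d.n_blue for d in self.draws)
            total = sum(d.size for d in self.draws)
            return blue / total
        if method == "mean":
            return float(np.mean([d.proportion_blue for d in self.draws]))
        raise ValueError(f"unknown method {method!r}")


def init_belief(rho: float) -> BeliefState:
    """Symmetric beta prior ``Beta(rho, rho)``; rho = 1 is the flat prior."""
    if rho < 1:
        raise ValueError("rho must be >= 1")
    return BeliefState(float(rho), float(rho))


def _weight(count: float, delta: float) -> float:
    # 0^delta == 0 for every delta (a zero count carries no evidence),
    # including the 0^0 corner.
    if count == 0:
        return 0.0
    return float(count) ** delta


def update_belief(belief: BeliefState, draw: SampleDraw, delta: float = 1.0) -> BeliefState:
    """Conjugate beta-binomial update with evidence-weight exponent delta.

    alpha' = alpha + B^delta, beta' = beta + R^delta; delta = 1 recovers the
    exact Bayesian update.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return BeliefState(
        belief.alpha + _weight(draw.n_blue, delta),
        belief.beta + _weight(draw.n_red, delta),
    )


def belief_moments(belief: BeliefState) -> tuple[float, float]:
    """Mean and variance of the belief distribution."""
    return belief.mean, belief.variance


def trial_trajectory(spec: ObserverSpec, draws) -> list[BeliefState]:
    """Belief states over one trial: prior followed by the five updates."""
    if spec.family == "rescorla_wagner":
        raise TypeError("Rescorla-Wagner tracks a point estimate, not a belief")
    states = [init_belief(spec.rho)]
    for draw in draws:
        states.append(update_belief(states[-1], draw, spec.delta))
    return states


def posterior_sd_trajectory(spec: ObserverSpec, draws) -> np.ndarray:
    """Posterior SD after each sample (length = number of draws)."""
    states = trial_trajectory(spec, draws)
    return np.array([s.sd for s in states[1:]])


def rw_trajectory(learning_rate: float, draws, init: float = 0.5) -> list[float]:
    """Rescorla-Wagner point-estimate trajectory (prior plus five updates)."""
    if not (0.0 <= learning_rate <= 1.0):
        raise ValueError("learning_rate must lie in [0, 1]")
    estimates = [float(init)]
    for draw in draws:
        err = estimates[-1] - draw.proportion_blue
        estimates.append(estimates[-1] - learning_rate * err)
    return estimates


def predicted_estimate(spec: ObserverSpec, draws) -> float:
    """Model-predicted report: posterior mean (Bayes) or final RW estimate."""
    if spec.family == "rescorla_wagner":
        return rw_trajectory(spec.params["learning_rate"], draws)[-1]
    return trial_trajectory(spec, draws)[-1].mean


def response_grid() -> np.ndarray:
    """Admissible reported values: 0, 0.01, ..., 1."""
    return np.round(np.arange(0, 101) * GRID_STEP, 2)


def _grid_bin_edges(reported: float) -> tuple[float, float]:
    # bins centered on grid values, half-width at the closed [0, 1] edges
    j = int(round(reported / GRID_STEP))
    lo = max(0.0, (j - 0.5) * GRID_STEP)
    hi = min(1.0, (j + 0.5) * GRID_STEP)
    return lo, hi


def _truncnorm_logpdf(x: float, mean: float, sigma: float) -> float:
    a, b = (0.0 - mean) / sigma, (1.0 - mean) / sigma
    return float(stats.truncnorm.logpdf(x, a, b, loc=mean, scale=sigma))


def response_loglik(spec: ObserverSpec, draws, reported: float) -> float:
    """Log-likelihood of one reported estimate under the response model.

    Sigma families: normal density centered on the model prediction,
    truncated (renormalized) to [0, 1]. Draw families: probability of the
    1/100-wide response bin under the final beta distribution.
    """
    if not (0.0 <= reported <= 1.0):
        raise ValueError("reported estimate must lie in [0, 1]")
    if spec.family in SIGMA_FAMILIES:
        sigma = spec.params["sigma"]
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        return _truncnorm_logpdf(reported, predicted_estimate(spec, draws), sigma)
    final = trial_trajectory(spec, draws)[-1]
    lo, hi = _grid_bin_edges(reported)
    p = special.betainc(final.alpha, final.beta, hi) - special.betainc(
        final.alpha, final.beta, lo
    )
    return float(np.log(np.maximum(p, 1e-300)))


def dataset_negloglik(spec: ObserverSpec, trials) -> float:
    """Joint negative log-likelihood over a subject's valid trials."""
    trials = [t for t in trials if t.valid]
    if not trials:
        raise ValueError("no valid trials")
    return -sum(response_loglik(spec, t.draws, t.reported_estimate) for t in trials)
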