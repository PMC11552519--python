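"""The generative learning core over harm-intent x self-interest states.

Two model families share one parameter vocabulary:

* ``classify_refine`` — two states per attribution dimension, initially at
  5% ("beneficial") and 95% ("detrimental") of the attribute range.  What
  each joint state implies about the dictator's policy is held as
  Dirichlet pseudo-counts over {fair, unfair} outcomes and is *refined* by
  crediting each observed split to states in proportion to the posterior
  belief that the state produced it.  Refinement is damped by
  trial-to-trial forgetting (``omega``) and generalises between dictators
  (``lambda_other``).
* ``classic`` — six fixed attribute levels per dimension (6x6 = 36 joint
  states); each state maps deterministically to a fairness policy, so
  learning is pure Bayesian filtering with no refinement.

Both are recursive Bayesian filters with identity state transitions:
a dictator's character is static within a block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from classify_refine.task_core import SplitOutcome

__all__ = [
    "AgentParams",
    "AttributeGrid",
    "LikelihoodCounts",
    "BeliefState",
    "PARAM_NAMES",
    "policy_fair_prob",
    "init_beliefs",
    "update_beliefs",
    "predict_fair",
    "marginal_attributions",
    "carry_over",
]

#: Canonical parameter order used by transforms, fitting and recovery.
PARAM_NAMES = (
    "pHI0", "pSI0", "dEv", "EvRat", "alphaPrec",
    "wH", "wS", "w0", "lambda_other", "aEv", "omega", "POCbias",
)

CLASSIFY_REFINE_LEVELS = (0.05, 0.95)
CLASSIC_LEVELS = tuple((2 * j + 1) / 12 for j in range(6))  # bin midpoints


@dataclass(frozen=True)
class AgentParams:
    """The twelve parameters governing one simulated or fitted session.

    Attributes
    ----------
    pHI0, pSI0
        Central tendency of the prior belief that the dictator is high in
        harmful intent / self-interest (``initHarmInt``, ``initSelfInt``).
    dEv
        Evidence (concentration) of the prior state belief
        (``IntentAttrEv``); shapes the discretised prior of the classic
        family, while the two-state family's prior is fixed by its mean.
    EvRat
        Ratio of prior HI evidence to SI evidence (``evidRatio``); the
        winning model fixes it at 1.
    alphaPrec
        Decision precision (inverse temperature) of the report channels
        (``decisPrec``); 0 yields uniform responding.
    wH, wS, w0
        Weights of HI and SI, and the intercept, in the dictator's
        logistic fairness policy (``wHarmInt``, ``wSelfInt``,
        ``fairnessB``).
    lambda_other
        Carry-over rate of refined likelihood counts from one dictator to
        the next; 0 = fresh start per dictator, 1 = full generalisation.
    aEv
        Typing confidence (``typingConf``): prior Dirichlet evidence on
        each state's outcome likelihood; high values slow refinement.
    omega
        Trial-to-trial learning retention (``learnRetn``); counts decay
        toward their initial values by factor ``omega`` per trial, 1 =
        perfect memory.
    POCbias
        Additive logit shift of attributions reported for nonwhite
        dictators, any sign; 0 in the winning model.
    """

    pHI0: float
    pSI0: float
    dEv: float
    EvRat: float
    alphaPrec: float
    wH: float
    wS: float
    w0: float
    lambda_other: float
    aEv: float
    omega: float
    POCbias: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pHI0", "pSI0"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("dEv", "EvRat", "alphaPrec", "aEv"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in ("lambda_other", "omega"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def replace(self, **updates) -> "AgentParams":
        return replace(self, **updates)


@dataclass(frozen=True)
class AttributeGrid:
    """The attribute levels each joint state assigns to HI and SI.

    Joint states are enumerated HI-major: ``s = i_hi * n_si + i_si``, with
    levels ordered low to high within a dimension.
    """

    hi_values: tuple[float, ...]
    si_values: tuple[float, ...]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("classify_refine", "classic"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        expected = (
            CLASSIFY_REFINE_LEVELS if self.kind == "classify_refine" else CLASSIC_LEVELS
        )
        for name, vals in (("hi_values", self.hi_values), ("si_values", self.si_values)):
            if len(vals) != len(expected):
                raise ValueError(
                    f"{self.kind} grid requires {len(expected)} {name}, got {len(vals)}"
                )
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            if not all(0.0 < v < 1.0 for v in vals):
                raise ValueError(f"{name} must lie in (0, 1)")

    @property
    def n_states(self) -> int:
        return len(self.hi_values) * len(self.si_values)

    def joint_hi(self) -> np.ndarray:
        """HI attribute value of each joint state (HI-major order)."""
        return np.repeat(self.hi_values, len(self.si_values))

    def joint_si(self) -> np.ndarray:
        return np.tile(self.si_values, len(self.hi_values))


@dataclass(frozen=True)
class LikelihoodCounts:
    """Dirichlet pseudo-counts defining p(outcome | state) per joint state.

    ``counts[:, 0]`` are fair counts, ``counts[:, 1]`` unfair.
    ``baseline_counts`` are the initial counts, the attractor of the
    forgetting operator.  The classic family carries ``fixed_fair_prob``
    instead: its likelihood never moves (infinite evidence).
    """

    counts: np.ndarray
    baseline_counts: np.ndarray
    fixed_fair_prob: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fixed_fair_prob is None and not np.all(self.counts > 0):
            raise ValueError("likelihood counts must be strictly positive")

    def fair_prob(self) -> np.ndarray:
        """Row-normalised probability of a fair split per state."""
        if self.fixed_fair_prob is not None:
            return self.fixed_fair_prob
        return self.counts[:, 0] / self.counts.sum(axis=1)


@dataclass(frozen=True)
class BeliefState:
    """Prior/posterior over joint states plus the outcome-likelihood map."""

    grid: AttributeGrid
    state_prior: np.ndarray
    state_posterior: np.ndarray
    likelihood: LikelihoodCounts

    def __post_init__(self) -> None:
        for name, v in (("state_prior", self.state_prior),
                        ("state_posterior", self.state_posterior)):
            if abs(float(np.sum(v)) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 (got {np.sum(v)!r})")


def policy_fair_prob(hi: float, si: float, w0: float, wH: float, wS: float) -> float:
    """Probability of a fair split under the dictator's logistic policy.

    sigma(w0 - wH*hi - wS*si): with positive weights, more harmful or more
    selfish characters split less fairly.
    """
    z = w0 - wH * hi - wS * si
    # numerically safe logistic
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def _dim_prior(mean: float, concentration: float, levels: tuple[float, ...]) -> np.ndarray:
    """Marginal prior over one dimension's attribute levels.

    Two levels: exactly (1-mean, mean).  Six levels: a Beta density with
    the given mean and concentration evaluated at the level values and
    normalised (a discretised Beta).
    """
    if len(levels) == 2:
        return np.array([1.0 - mean, mean])
    a = mean * concentration
    b = (1.0 - mean) * concentration
    x = np.asarray(levels)
    logpdf = (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x)
    w = np.exp(logpdf - logpdf.max())
    return w / w.sum()


def init_beliefs(params: AgentParams, kind: str = "classify_refine") -> BeliefState:
    """Belief state at the start of a participant's first dictator block.

    The joint prior is the outer product of independent HI and SI
    marginals (prior evidence ``dEv * EvRat`` for HI, ``dEv`` for SI).
    Likelihood counts place ``aEv`` pseudo-observations per state, split
    between fair and unfair according to that state's policy fairness; the
    classic family instead pins the likelihood at the policy values.
    """
    if kind == "classify_refine":
        levels = CLASSIFY_REFINE_LEVELS
    elif kind == "classic":
        levels = CLASSIC_LEVELS
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    grid = AttributeGrid(hi_values=levels, si_values=levels, kind=kind)

    hi_marg = _dim_prior(params.pHI0, params.dEv * params.EvRat, levels)
    si_marg = _dim_prior(params.pSI0, params.dEv, levels)
    prior = np.outer(hi_marg, si_marg).ravel()

    pf = np.array(
        [
            policy_fair_prob(hi, si, params.w0, params.wH, params.wS)
            for hi, si in zip(grid.joint_hi(), grid.joint_si())
        ]
    )
    if kind == "classic":
        counts = np.full((grid.n_states, 2), np.inf)
        likelihood = LikelihoodCounts(
            counts=counts, baseline_counts=counts, fixed_fair_prob=pf
        )
    else:
        counts = params.aEv * np.column_stack([pf, 1.0 - pf])
        likelihood = LikelihoodCounts(counts=counts, baseline_counts=counts.copy())
    return BeliefState(
        grid=grid,
        state_prior=prior,
        state_posterior=prior.copy(),
        likelihood=likelihood,
    )


def update_beliefs(belief: BeliefState, outcome: SplitOutcome,
                   params: AgentParams) -> BeliefState:
    """One trial of the recursive filter: Bayes, credit, forget.

    1. posterior(s) ∝ prior(s) * p̂(outcome | s);
    2. classify-refine only: counts(s, outcome) += posterior(s)
       (posterior-weighted credit assignment);
    3. classify-refine only: counts decay toward baseline by ``omega``;
    4. the posterior becomes the next trial's prior (identity
       transitions: the dictator's character is static).
    """
    pf = belief.likelihood.fair_prob()
    lik = pf if outcome.is_fair else 1.0 - pf
    unnorm = belief.state_prior * lik
    total = float(unnorm.sum())
    if not total > 0.0:
        raise FloatingPointError(
            "all states assign zero probability to the observed outcome"
        )
    posterior = unnorm / total

    likelihood = belief.likelihood
    if likelihood.fixed_fair_prob is None:
        counts = likelihood.counts.copy()
        counts[:, 0 if outcome.is_fair else 1] += posterior
        base = likelihood.baseline_counts
        counts = base + params.omega * (counts - base)
        likelihood = LikelihoodCounts(counts=counts, baseline_counts=base)

    return BeliefState(
        grid=belief.grid,
        state_prior=posterior.copy(),
        state_posterior=posterior,
        likelihood=likelihood,
    )


def predict_fair(belief: BeliefState) -> float:
    """One-step-ahead predictive probability of a fair split.

    Uses the current state *prior* (the belief held before the trial's
    outcome is shown), matching the expectation report's timing.
    """
    return float(np.dot(belief.state_prior, belief.likelihood.fair_prob()))


def marginal_attributions(belief: BeliefState) -> tuple[float, float]:
    """(HI, SI) attribution values implied by the current posterior.

    Classify-refine: posterior mass on the detrimental (high) state of
    each dimension.  Classic: posterior-expected attribute value.
    """
    q = belief.state_posterior
    if belief.grid.kind == "classify_refine":
        n_si = len(belief.grid.si_values)
        hi_mass = float(q.reshape(-1, n_si)[1, :].sum())
        si_mass = float(q.reshape(-1, n_si)[:, 1].sum())
        return hi_mass, si_mass
    hi = float(np.dot(q, belief.grid.joint_hi()))
    si = float(np.dot(q, belief.grid.joint_si()))
    return hi, si


def carry_over(end_belief: BeliefState, params: AgentParams,
               fresh: BeliefState) -> BeliefState:
    """Belief at the start of the next dictator block.

    Refined likelihood counts generalise to the new dictator at rate
    ``lambda_other``; state beliefs reset to the fresh prior (a new
    dictator's character is unknown).
    """
    if fresh.likelihood.fixed_fair_prob is not None:
        return fresh
    base = fresh.likelihood.baseline_counts
    counts = base + params.lambda_other * (end_belief.likelihood.counts - base)
    return BeliefState(
        grid=fresh.grid,
        state_prior=fresh.state_prior.copy(),
        state_posterior=fresh.state_prior.copy(),
        likelihood=LikelihoodCounts(counts=counts, baseline_counts=base.copy()),
    )
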