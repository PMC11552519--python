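"""Parameter transforms, priors, session likelihoods and MAP fitting.

Fitting maximises log-likelihood plus a weakly informative log-prior
(defined over native parameter space) with respect to transformed
coordinates: logit for probabilities and rates, log for positive
magnitudes, identity for the policy weights and the POC bias.  The
optimizer is an adaptive multistart coordinate grid search — a coarse
grid per free dimension is evaluated, recentred on the best point and
contracted until the grid step falls below tolerance.  Gradient-based
optimisers are deliberately not used as the primary fitter: the
likelihood surface of these learning models is multimodal and grid
refinement is robust to that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from classify_refine.agent_models import (
    PARAM_NAMES,
    AgentParams,
    CLASSIC_LEVELS,
    CLASSIFY_REFINE_LEVELS,
    policy_fair_prob,
)
from classify_refine._engine import session_loglik_kernel
from classify_refine.model_space import ModelSpec
from classify_refine.response_models import DEFAULT_SCALE, ReportScale, snap_to_bin
from classify_refine.task_core import Session

__all__ = [
    "FitConfig",
    "FitResult",
    "transform_params",
    "untransform_params",
    "transform_value",
    "untransform_value",
    "log_prior",
    "session_loglik",
    "map_fit",
    "PRIOR_MODE",
]

LOGIT_PARAMS = ("pHI0", "pSI0", "omega", "lambda_other")
LOG_PARAMS = ("dEv", "aEv", "alphaPrec", "EvRat")
IDENTITY_PARAMS = ("wH", "wS", "w0", "POCbias")

_EPS = 1e-12  # boundary clamp before logit/log


def _logit(p: float) -> float:
    p = min(max(p, _EPS), 1.0 - _EPS)
    return math.log(p / (1.0 - p))


def _expit(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def transform_value(name: str, value: float) -> float:
    """Map one parameter to its unconstrained coordinate."""
    if name in LOGIT_PARAMS:
        return _logit(value)
    if name in LOG_PARAMS:
        return math.log(max(value, _EPS))
    return value


def untransform_value(name: str, z: float) -> float:
    if name in LOGIT_PARAMS:
        return _expit(z)
    if name in LOG_PARAMS:
        return math.exp(z)
    return z


def transform_params(params: AgentParams) -> np.ndarray:
    """All 12 parameters as an unconstrained vector (canonical order)."""
    return np.array(
        [transform_value(n, getattr(params, n)) for n in PARAM_NAMES]
    )


def untransform_params(vector) -> AgentParams:
    vals = {n: untransform_value(n, float(z)) for n, z in zip(PARAM_NAMES, vector)}
    return AgentParams(**vals)


# ---------------------------------------------------------------------------
# Weakly informative priors (native space).  Broad by design; overridable
# hyperparameters live here in one table.
#   Beta(1.2, 1.2)      : pHI0, pSI0, omega, lambda_other
#   Gamma(k=2, theta=2) : dEv, aEv, alphaPrec, EvRat
#   Normal(0, 2^2)      : wH, wS, w0, POCbias
# ---------------------------------------------------------------------------

_BETA_A = _BETA_B = 1.2
_GAMMA_K, _GAMMA_THETA = 2.0, 2.0
_NORMAL_SD = 2.0

_LN_BETA_NORM = math.lgamma(_BETA_A) + math.lgamma(_BETA_B) - math.lgamma(_BETA_A + _BETA_B)
_LN_GAMMA_NORM = math.lgamma(_GAMMA_K) + _GAMMA_K * math.log(_GAMMA_THETA)
_LN_NORMAL_NORM = math.log(_NORMAL_SD * math.sqrt(2.0 * math.pi))

#: Joint mode of the default priors; the first grid-search start point.
PRIOR_MODE = AgentParams(
    pHI0=0.5, pSI0=0.5, dEv=2.0, EvRat=2.0, alphaPrec=2.0,
    wH=0.0, wS=0.0, w0=0.0, lambda_other=0.5, aEv=2.0, omega=0.5, POCbias=0.0,
)


def _prior_logpdf(name: str, value: float) -> float:
    if name in LOGIT_PARAMS:
        v = min(max(value, _EPS), 1.0 - _EPS)
        return (_BETA_A - 1.0) * math.log(v) + (_BETA_B - 1.0) * math.log1p(-v) - _LN_BETA_NORM
    if name in LOG_PARAMS:
        if value <= 0.0:
            return -math.inf
        return (_GAMMA_K - 1.0) * math.log(value) - value / _GAMMA_THETA - _LN_GAMMA_NORM
    return -0.5 * (value / _NORMAL_SD) ** 2 - _LN_NORMAL_NORM


def log_prior(params: AgentParams) -> float:
    """Sum of independent weakly informative prior log-densities."""
    return sum(_prior_logpdf(n, getattr(params, n)) for n in PARAM_NAMES)


def _sample_prior(rng: np.random.Generator) -> AgentParams:
    vals = {}
    for n in PARAM_NAMES:
        if n in LOGIT_PARAMS:
            vals[n] = float(rng.beta(_BETA_A, _BETA_B))
        elif n in LOG_PARAMS:
            vals[n] = float(rng.gamma(_GAMMA_K, _GAMMA_THETA))
        else:
            vals[n] = float(rng.normal(0.0, _NORMAL_SD))
    # keep draws away from hard boundaries
    for n in LOGIT_PARAMS:
        vals[n] = min(max(vals[n], 1e-4), 1.0 - 1e-4)
    for n in LOG_PARAMS:
        vals[n] = max(vals[n], 1e-4)
    return AgentParams(**vals)


# ---------------------------------------------------------------------------
# Session likelihood
# ---------------------------------------------------------------------------

class SessionArrays(NamedTuple):
    """Flat per-trial arrays extracted once per session for the kernel."""

    outcomes: np.ndarray
    exp_bin: np.ndarray
    hi_bin: np.ndarray
    si_bin: np.ndarray
    nonwhite: np.ndarray
    block_start: np.ndarray
    bins: np.ndarray
    use_exp: bool
    use_hi: bool
    use_si: bool

    @property
    def n_datapoints(self) -> int:
        n_channels = int(self.use_exp) + int(self.use_hi) + int(self.use_si)
        return n_channels * len(self.outcomes)


def prepare_session_arrays(session: Session,
                           channels: frozenset[str],
                           scale: ReportScale = DEFAULT_SCALE) -> SessionArrays:
    outcomes, exp_b, hi_b, si_b, nonw, starts = [], [], [], [], [], [0]
    for block in session.blocks:
        for t in block.trials:
            outcomes.append(1 if t.outcome.is_fair else 0)
            exp_b.append(snap_to_bin(t.expectation_report, scale))
            hi_b.append(snap_to_bin(t.hi_report, scale))
            si_b.append(snap_to_bin(t.si_report, scale))
            nonw.append(1 if block.is_nonwhite else 0)
        starts.append(len(outcomes))
    return SessionArrays(
        outcomes=np.asarray(outcomes, dtype=np.int64),
        exp_bin=np.asarray(exp_b, dtype=np.int64),
        hi_bin=np.asarray(hi_b, dtype=np.int64),
        si_bin=np.asarray(si_b, dtype=np.int64),
        nonwhite=np.asarray(nonw, dtype=np.int64),
        block_start=np.asarray(starts, dtype=np.int64),
        bins=np.asarray(scale.bin_values, dtype=np.float64),
        use_exp="expectation" in channels,
        use_hi="HI" in channels,
        use_si="SI" in channels,
    )


def _dim_prior_arr(mean: float, conc: float, levels: np.ndarray) -> np.ndarray:
    if len(levels) == 2:
        return np.array([1.0 - mean, mean])
    a, b = mean * conc, (1.0 - mean) * conc
    logpdf = (a - 1.0) * np.log(levels) + (b - 1.0) * np.log1p(-levels)
    w = np.exp(logpdf - logpdf.max())
    return w / w.sum()


def _state_arrays(params: AgentParams, kind: str):
    levels = np.asarray(
        CLASSIFY_REFINE_LEVELS if kind == "classify_refine" else CLASSIC_LEVELS
    )
    n = len(levels)
    hi_marg = _dim_prior_arr(params.pHI0, params.dEv * params.EvRat, levels)
    si_marg = _dim_prior_arr(params.pSI0, params.dEv, levels)
    prior0 = np.outer(hi_marg, si_marg).ravel()
    joint_hi = np.repeat(levels, n)
    joint_si = np.tile(levels, n)
    pf0 = np.array(
        [
            policy_fair_prob(h, s, params.w0, params.wH, params.wS)
            for h, s in zip(joint_hi, joint_si)
        ]
    )
    if kind == "classify_refine":
        hi_w = np.repeat(np.array([0.0, 1.0]), 2)
        si_w = np.tile(np.array([0.0, 1.0]), 2)
        learn = True
    else:
        hi_w, si_w = joint_hi, joint_si
        learn = False
    return prior0, pf0, hi_w, si_w, learn


def _loglik_arrays(params: AgentParams, arrays: SessionArrays, kind: str):
    prior0, pf0, hi_w, si_w, learn = _state_arrays(params, kind)
    return session_loglik_kernel(
        prior0, pf0, hi_w, si_w, learn,
        params.aEv, params.omega, params.lambda_other,
        params.alphaPrec, params.POCbias,
        arrays.outcomes, arrays.exp_bin, arrays.hi_bin, arrays.si_bin,
        arrays.nonwhite, arrays.block_start, arrays.bins,
        arrays.use_exp, arrays.use_hi, arrays.use_si,
    )


def session_loglik(params: AgentParams, session: Session, spec: ModelSpec,
                   scale: ReportScale = DEFAULT_SCALE) -> float:
    """Log-likelihood of all reports in one session under one model.

    Iterates blocks in presentation order, running belief initialisation,
    trial-wise updating and between-dictator carry-over, and accumulates
    the report log-likelihoods over the channels the model includes.
    """
    arrays = prepare_session_arrays(session, spec.channels, scale)
    ll, fail = _loglik_arrays(params, arrays, spec.kind)
    if fail >= 0:
        block = int(np.searchsorted(arrays.block_start, fail, side="right"))
        trial = fail - int(arrays.block_start[block - 1]) + 1
        raise FloatingPointError(
            f"likelihood degenerate at block {block}, trial {trial}"
        )
    return float(ll)


# ---------------------------------------------------------------------------
# MAP fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Adaptive multistart coordinate-grid-search settings.

    ``n_starts`` initial points (prior mode plus seeded prior draws); per
    sweep each free dimension is scanned on ``n_grid`` points spanning
    +/- its current radius; radii contract by ``contraction`` unless the
    best point sat on the grid edge.  Stops when every grid step is below
    ``tol`` (transformed space) or after ``max_sweeps``.
    """

    n_starts: int = 8
    n_grid: int = 7
    contraction: float = 0.5
    init_radius: float = 2.0
    tol: float = 1e-3
    max_sweeps: int = 40
    polish_maxiter: int = 200
    seed: int = 0


@dataclass
class FitResult:
    """MAP estimate with likelihood, posterior and optimizer diagnostics."""

    map_params: AgentParams
    loglik: float
    logpost: float
    n_datapoints: int
    n_free_params: int
    optimizer_trace: list = field(default_factory=list)
    converged: bool = False
    seed: int = 0


def _free_names(spec: ModelSpec) -> list[str]:
    return [n for n in PARAM_NAMES if n in spec.free_params]


def _build_params(free_names, x_free, spec: ModelSpec) -> AgentParams | None:
    vals = dict(spec.fixed_values)
    for n, z in zip(free_names, x_free):
        vals[n] = untransform_value(n, float(z))
    for n in PARAM_NAMES:
        vals.setdefault(n, getattr(PRIOR_MODE, n))
    try:
        return AgentParams(**vals)
    except (ValueError, OverflowError):
        return None


def map_fit(session: Session, spec: ModelSpec,
            config: FitConfig | None = None,
            scale: ReportScale = DEFAULT_SCALE) -> FitResult:
    """MAP fit of one session by adaptive multistart coordinate grid search.

    Deterministic given ``config`` (including its seed).  If every start
    yields a non-finite objective the result is flagged unconverged with
    ``loglik = -inf`` rather than raising.
    """
    config = config or FitConfig()
    arrays = prepare_session_arrays(session, spec.channels, scale)
    free = _free_names(spec)

    def objective(x_free) -> float:
        params = _build_params(free, x_free, spec)
        if params is None:
            return -math.inf
        ll, fail = _loglik_arrays(params, arrays, spec.kind)
        if fail >= 0 or not math.isfinite(ll):
            return -math.inf
        return ll + log_prior(params)

    if not free:
        params = _build_params(free, [], spec)
        ll, fail = _loglik_arrays(params, arrays, spec.kind)
        ll = -math.inf if fail >= 0 else float(ll)
        return FitResult(
            map_params=params, loglik=ll, logpost=ll + log_prior(params),
            n_datapoints=arrays.n_datapoints, n_free_params=0,
            optimizer_trace=[], converged=True, seed=config.seed,
        )

    rng = np.random.default_rng(config.seed)
    starts = [PRIOR_MODE] + [_sample_prior(rng) for _ in range(config.n_starts - 1)]

    best_x, best_f, best_trace, best_converged = None, -math.inf, [], False
    for start in starts:
        x0 = np.array([transform_value(n, getattr(start, n)) for n in free])
        x, f, trace, converged = _grid_refine(objective, x0, config)
        if f > best_f:
            best_x, best_f, best_trace, best_converged = x, f, trace, converged

    if best_x is None or not math.isfinite(best_f):
        return FitResult(
            map_params=PRIOR_MODE, loglik=-math.inf, logpost=-math.inf,
            n_datapoints=arrays.n_datapoints, n_free_params=len(free),
            optimizer_trace=best_trace, converged=False, seed=config.seed,
        )

    # Derivative-free polish of the grid optimum.  Coordinate search is
    # slow along the ridges these likelihoods exhibit (e.g. typing
    # confidence vs. retention); a simplex run from the grid optimum
    # handles those, and the polished point is kept only if it improves.
    if config.polish_maxiter > 0:
        from scipy import optimize

        res = optimize.minimize(
            lambda z: -objective(z), best_x, method="Nelder-Mead",
            options={"maxiter": config.polish_maxiter, "xatol": config.tol,
                     "fatol": 1e-6},
        )
        if math.isfinite(res.fun) and -res.fun > best_f:
            best_x, best_f = res.x, -res.fun
            best_trace = best_trace + [(res.x.copy(), -res.fun)]

    map_params = _build_params(free, best_x, spec)
    ll, _ = _loglik_arrays(map_params, arrays, spec.kind)
    return FitResult(
        map_params=map_params, loglik=float(ll),
        logpost=float(ll) + log_prior(map_params),
        n_datapoints=arrays.n_datapoints, n_free_params=len(free),
        optimizer_trace=best_trace, converged=best_converged,
        seed=config.seed,
    )


def _grid_refine(objective, x0: np.ndarray, config: FitConfig):
    """Coordinate grid refinement from one start; monotone in the objective."""
    x = x0.copy()
    f = objective(x)
    n = len(x)
    radius = np.full(n, float(config.init_radius))
    trace = []
    converged = False
    for _ in range(config.max_sweeps):
        at_edge = np.zeros(n, dtype=bool)
        for d in range(n):
            offsets = np.linspace(-radius[d], radius[d], config.n_grid)
            best_off, best_val = 0.0, f
            for off in offsets:
                if off == 0.0:
                    continue
                cand = x.copy()
                cand[d] += off
                val = objective(cand)
                if val > best_val:
                    best_off, best_val = off, val
            if best_off != 0.0:
                x[d] += best_off
                f = best_val
                if abs(best_off) >= radius[d] - 1e-15:
                    at_edge[d] = True
        step = 2.0 * radius / (config.n_grid - 1)
        trace.append((x.copy(), f))
        if np.all(step < config.tol):
            converged = True
            break
        radius = np.where(at_edge, radius, radius * config.contraction)
    return x, f, trace, converged
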