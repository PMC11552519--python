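"""Report channels: from core beliefs to the three per-trial reports.

Each report (fairness expectation, HI attribution, SI attribution) is a
draw from a discretised softmax over response bins, with probability
proportional to ``exp(-alphaPrec * (bin - model_value)^2)``.  A single
decision precision ``alphaPrec`` is shared by all three channels; 0 gives
uniform responding and large values concentrate mass on the bin nearest
the model value.

For nonwhite dictators the attribution values passed from the learning
core to the reporting process are shifted by ``POCbias`` on the log-odds
scale, in either direction; the expectation channel is unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from classify_refine.agent_models import (
    AgentParams,
    BeliefState,
    marginal_attributions,
    predict_fair,
)
from classify_refine.task_core import Trial

__all__ = [
    "ReportScale",
    "DEFAULT_SCALE",
    "apply_poc_bias",
    "report_distribution",
    "snap_to_bin",
    "trial_loglik",
]

_CLAMP = 1e-6
PROB_FLOOR = 1e-12  # channel probabilities are floored before log


@dataclass(frozen=True)
class ReportScale:
    """The discrete response scale participants answer on."""

    bin_values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = self.bin_values
        if len(v) < 2:
            raise ValueError("a report scale needs at least 2 bins")
        if v[0] != 0.0 or v[-1] != 1.0:
            raise ValueError("bin_values must start at 0 and end at 1")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("bin_values must be strictly increasing")

    @classmethod
    def uniform(cls, n_bins: int = 11) -> "ReportScale":
        return cls(tuple(j / (n_bins - 1) for j in range(n_bins)))

    @property
    def n_bins(self) -> int:
        return len(self.bin_values)


DEFAULT_SCALE = ReportScale.uniform(11)


def apply_poc_bias(value: float, poc_bias: float, is_nonwhite: bool) -> float:
    """Shift an attribution by ``poc_bias`` log-odds for nonwhite dictators.

    White dictators (and zero bias) pass through unchanged.  Values at the
    boundary are clamped to [1e-6, 1 - 1e-6] before the logit.
    """
    if not is_nonwhite or poc_bias == 0.0:
        return value
    v = min(max(value, _CLAMP), 1.0 - _CLAMP)
    z = math.log(v / (1.0 - v)) + poc_bias
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def report_distribution(model_value: float, alpha_prec: float,
                        scale: ReportScale = DEFAULT_SCALE) -> np.ndarray:
    """Channel distribution over response bins for one model value."""
    bins = np.asarray(scale.bin_values)
    d2 = (bins - model_value) ** 2
    w = np.exp(-alpha_prec * (d2 - d2.min()))  # stabilised softmax
    return w / w.sum()


def snap_to_bin(report: float, scale: ReportScale = DEFAULT_SCALE) -> int:
    """Index of the scale bin nearest to a continuous report."""
    bins = np.asarray(scale.bin_values)
    return int(np.argmin(np.abs(bins - report)))


def _channel_loglik(model_value: float, report: float, alpha_prec: float,
                    scale: ReportScale) -> float:
    p = report_distribution(model_value, alpha_prec, scale)
    return float(np.log(max(p[snap_to_bin(report, scale)], PROB_FLOOR)))


def trial_loglik(belief_before: BeliefState, belief_after: BeliefState,
                 trial: Trial, params: AgentParams, is_nonwhite: bool,
                 scale: ReportScale = DEFAULT_SCALE,
                 channels: frozenset[str] = frozenset({"expectation", "HI", "SI"}),
                 ) -> float:
    """Log-likelihood of one trial's reports given the agent's beliefs.

    The expectation report is scored against the pre-outcome predictive
    (the expectation stage precedes the split); HI and SI reports against
    the post-outcome marginal attributions, POC-biased where applicable.
    Reports are snapped to the nearest scale bin.
    """
    total = 0.0
    if "expectation" in channels:
        total += _channel_loglik(
            predict_fair(belief_before), trial.expectation_report,
            params.alphaPrec, scale,
        )
    if "HI" in channels or "SI" in channels:
        hi_val, si_val = marginal_attributions(belief_after)
        if "HI" in channels:
            total += _channel_loglik(
                apply_poc_bias(hi_val, params.POCbias, is_nonwhite),
                trial.hi_report, params.alphaPrec, scale,
            )
        if "SI" in channels:
            total += _channel_loglik(
                apply_poc_bias(si_val, params.POCbias, is_nonwhite),
                trial.si_report, params.alphaPrec, scale,
            )
    return total
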