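"""Model registry, information criteria and BIC-based model comparison.

Each :class:`ModelSpec` names a model family (classify-refine vs. the
classic 6x6 learner), partitions the twelve parameters into free, fixed
and sample-shared sets, and selects which report channels enter the
likelihood.  Per-participant BIC (with a small-sample correction) and AIC
are computed from MAP fits; comparisons report medians, rank tests and
counts of participants exceeding a |dBIC| evidence threshold
(conventionally 6, "modest evidence").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from classify_refine.agent_models import PARAM_NAMES

__all__ = [
    "ModelSpec",
    "ComparisonResult",
    "information_criteria",
    "compare_models",
    "compare_bic",
    "registry",
    "get_model",
]

ALL_CHANNELS = frozenset({"expectation", "HI", "SI"})


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are free, fixed or shared, and which channels count."""

    name: str
    kind: str
    free_params: frozenset[str]
    fixed_values: dict[str, float] = field(default_factory=dict)
    shared_params: frozenset[str] = frozenset()
    channels: frozenset[str] = ALL_CHANNELS

    def __post_init__(self) -> None:
        if self.kind not in ("classify_refine", "classic"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        free = frozenset(self.free_params)
        fixed = frozenset(self.fixed_values)
        shared = frozenset(self.shared_params)
        object.__setattr__(self, "free_params", free)
        object.__setattr__(self, "shared_params", shared)
        object.__setattr__(self, "channels", frozenset(self.channels))
        covered = free | fixed | shared
        if covered != set(PARAM_NAMES) or (free & fixed) or (free & shared) or (fixed & shared):
            raise ValueError(
                f"model {self.name!r}: free/fixed/shared must partition "
                f"{sorted(PARAM_NAMES)}; got free={sorted(free)}, "
                f"fixed={sorted(fixed)}, shared={sorted(shared)}"
            )
        if not self.channels or not self.channels <= ALL_CHANNELS:
            raise ValueError(
                f"channels must be a nonempty subset of {sorted(ALL_CHANNELS)}"
            )

    @property
    def n_free(self) -> int:
        return len(self.free_params)


@dataclass
class ComparisonResult:
    """Per-participant BIC comparison of two fitted models (A vs. B)."""

    participants: list[str]
    bic_a: np.ndarray
    bic_b: np.ndarray
    median_a: float
    median_b: float
    rank_sum_stat: float
    rank_sum_p: float
    signed_rank_stat: float
    signed_rank_p: float
    threshold: float
    n_favor_a: int      # dBIC = BIC_A - BIC_B <= -threshold
    n_favor_b: int      # dBIC >= +threshold
    n_indeterminate: int


def effective_k(spec: ModelSpec, n_free: int, n_i: int,
                sample_size_total: int | None = None,
                n_participants: int = 1) -> float:
    """Per-participant parameter count including the shared-parameter share.

    A sample-shared parameter contributes
    ``ln(n_total) / (n_participants * ln(n_i))`` equivalent free-parameter
    units per participant, so its penalty summed over the sample is
    ``ln(n_total)``.
    """
    k_i = float(n_free)
    if spec.shared_params:
        if sample_size_total is None:
            sample_size_total = n_participants * n_i
        k_i += (
            len(spec.shared_params) / n_participants
            * math.log(sample_size_total) / math.log(n_i)
        )
    return k_i


def information_criteria(fit, spec: ModelSpec, sample_size_total: int | None = None,
                         n_participants: int = 1) -> tuple[float, float]:
    """Per-participant small-sample-corrected BIC and AIC for one MAP fit.

    BIC_i = k_i ln(n_i) - 2 loglik + 2 k_i (k_i + 1) / (n_i - k_i - 1).

    A parameter fitted once across the whole sample contributes an
    equivalent per-participant penalty of
    ``ln(n_total) / (n_participants * ln(n_i))`` free-parameter units, so
    that the sample-summed penalty for that parameter equals
    ``ln(n_total)`` — consistent with BIC/2 approximating log model
    evidence.  ``fit`` needs ``loglik``, ``n_datapoints`` and
    ``n_free_params`` attributes.
    """
    n_i = fit.n_datapoints
    k_i = effective_k(spec, fit.n_free_params, n_i, sample_size_total,
                      n_participants)
    if n_i <= k_i + 1:
        raise ValueError(
            f"small-sample correction undefined: n={n_i} <= k+1={k_i + 1}"
        )
    bic = k_i * math.log(n_i) - 2.0 * fit.loglik + 2.0 * k_i * (k_i + 1.0) / (n_i - k_i - 1.0)
    aic = 2.0 * k_i - 2.0 * fit.loglik
    return bic, aic


def compare_models(fits_a: dict, fits_b: dict, spec_a: ModelSpec, spec_b: ModelSpec,
                   threshold: float = 6.0) -> ComparisonResult:
    """Compare two models fitted to the same participants by BIC.

    ``fits_a``/``fits_b`` map participant id -> FitResult.  Reports both
    the two-sample rank-sum test and the paired signed-rank test on the
    BIC samples, and counts participants for whom either model leads by
    at least ``threshold`` BIC points.
    """
    ids_a, ids_b = set(fits_a), set(fits_b)
    if ids_a != ids_b:
        diff = sorted(ids_a.symmetric_difference(ids_b))
        raise ValueError(f"participant mismatch between fits: {diff}")
    participants = sorted(fits_a)
    n = len(participants)
    bic_a = np.array([information_criteria(fits_a[p], spec_a, n_participants=n)[0]
                      for p in participants])
    bic_b = np.array([information_criteria(fits_b[p], spec_b, n_participants=n)[0]
                      for p in participants])
    return compare_bic(participants, bic_a, bic_b, threshold=threshold)


def compare_bic(participants: list[str], bic_a, bic_b,
                threshold: float = 6.0) -> ComparisonResult:
    """BIC comparison from precomputed per-participant BIC values."""
    bic_a = np.asarray(bic_a, dtype=float)
    bic_b = np.asarray(bic_b, dtype=float)
    n = len(participants)
    delta = bic_a - bic_b
    rank_sum = stats.ranksums(bic_a, bic_b)
    if np.allclose(delta, 0.0):
        signed_stat, signed_p = 0.0, 1.0
    else:
        signed = stats.wilcoxon(bic_a, bic_b)
        signed_stat, signed_p = float(signed.statistic), float(signed.pvalue)
    n_a = int(np.sum(delta <= -threshold))
    n_b = int(np.sum(delta >= threshold))
    return ComparisonResult(
        participants=participants,
        bic_a=bic_a,
        bic_b=bic_b,
        median_a=float(np.median(bic_a)),
        median_b=float(np.median(bic_b)),
        rank_sum_stat=float(rank_sum.statistic),
        rank_sum_p=float(rank_sum.pvalue),
        signed_rank_stat=signed_stat,
        signed_rank_p=signed_p,
        threshold=threshold,
        n_favor_a=n_a,
        n_favor_b=n_b,
        n_indeterminate=n - n_a - n_b,
    )


def _cr_spec(name: str, fixed: dict[str, float],
             channels: frozenset[str] = ALL_CHANNELS) -> ModelSpec:
    free = frozenset(set(PARAM_NAMES) - set(fixed))
    return ModelSpec(name=name, kind="classify_refine", free_params=free,
                     fixed_values=fixed, channels=channels)


def registry() -> list[ModelSpec]:
    """The model space compared in the analyses.

    * ``classic-full`` — 6x6 fixed-grid learner; the refinement
      parameters (aEv, omega, lambda_other) have no effect in this family
      and are fixed, as is the POC bias, leaving 8 free parameters.
    * ``classify-refine-full`` — all 12 parameters free.
    * ``winning`` — classify-refine with the HI:SI prior-evidence ratio
      fixed at 1 and no POC bias (two parameters fewer than full).
    * ``winning-poc`` — winning plus a free POC bias.
    * ``no-lambda-other`` / ``no-omega`` — winning without carry-over /
      without forgetting.
    * ``winning-attrib-only`` — winning scored on the HI and SI
      attribution reports only (96 datapoints per session).
    """
    classic_fixed = {"aEv": 1e6, "omega": 1.0, "lambda_other": 0.0, "POCbias": 0.0}
    return [
        ModelSpec(
            name="classic-full", kind="classic",
            free_params=frozenset(set(PARAM_NAMES) - set(classic_fixed)),
            fixed_values=classic_fixed,
        ),
        _cr_spec("classify-refine-full", {}),
        _cr_spec("winning", {"EvRat": 1.0, "POCbias": 0.0}),
        _cr_spec("winning-poc", {"EvRat": 1.0}),
        _cr_spec("no-lambda-other", {"EvRat": 1.0, "POCbias": 0.0, "lambda_other": 0.0}),
        _cr_spec("no-omega", {"EvRat": 1.0, "POCbias": 0.0, "omega": 1.0}),
        _cr_spec("winning-attrib-only", {"EvRat": 1.0, "POCbias": 0.0},
                 channels=frozenset({"HI", "SI"})),
    ]


def get_model(name: str) -> ModelSpec:
    for spec in registry():
        if spec.name == name:
            return spec
    raise KeyError(f"no registered model named {name!r}")
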