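"""Second-level statistics on fitted parameters and average task measures.

The analysis contract is: robust (Huber M-estimation) regression for the
stability hypothesis tests, ordinary-least-squares diagnostics (Cook's
distance > 1 or |standardised residual| > 3, strict inequalities) to
screen outliers, and random-intercept linear mixed models for the
wave x drug treatment contrasts.  Everything is a thin layer over
statsmodels; p-values are reported uncorrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from classify_refine.task_core import Session

__all__ = [
    "average_measures",
    "StabilityResult",
    "stability_regression",
    "outlier_screen",
    "MixedModelResult",
    "wave_drug_mixed_model",
]


def average_measures(session: Session) -> tuple[float, float, float]:
    """(HIAv, SIAv, predAv): session means of the three reports, 48 trials."""
    hi, si, pred = [], [], []
    for block in session.blocks:
        for t in block.trials:
            hi.append(t.hi_report)
            si.append(t.si_report)
            pred.append(t.expectation_report)
    return float(np.mean(hi)), float(np.mean(si)), float(np.mean(pred))


@dataclass
class StabilityResult:
    """Robust-regression stability test of follow-up on baseline values."""

    table: pd.DataFrame          # coef, se, tvalue per term (robust fit)
    baseline_coef: float
    baseline_t: float
    ols_adj_r2: float
    n: int


def _design_frame(baseline, covariates: pd.DataFrame | None) -> pd.DataFrame:
    X = pd.DataFrame({"baseline": np.asarray(baseline, dtype=float)})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        for col in cov.columns:
            series = cov[col]
            if series.dtype == object or str(series.dtype) == "category":
                dummies = pd.get_dummies(series, prefix=col, drop_first=True)
                X = pd.concat([X, dummies.astype(float)], axis=1)
            else:
                X[col] = series.astype(float)
    return X


def stability_regression(follow, baseline,
                         covariates: pd.DataFrame | None = None) -> StabilityResult:
    """Regress follow-up values on baseline with covariate control.

    The hypothesis test is the t-value of the baseline coefficient in a
    Huber robust regression; the adjusted R^2 comes from the equivalent
    OLS fit (robust fits have no conventional R^2).
    """
    y = np.asarray(follow, dtype=float)
    X = _design_frame(baseline, covariates)
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {Xc.shape[1]} "
            f"columns: {list(Xc.columns)})"
        )
    rlm = sm.RLM(y, Xc, M=sm.robust.norms.HuberT()).fit()
    ols = sm.OLS(y, Xc).fit()
    table = pd.DataFrame(
        {"coef": rlm.params, "se": rlm.bse, "tvalue": rlm.tvalues}
    )
    return StabilityResult(
        table=table,
        baseline_coef=float(rlm.params["baseline"]),
        baseline_t=float(rlm.tvalues["baseline"]),
        ols_adj_r2=float(ols.rsquared_adj),
        n=len(y),
    )


def outlier_screen(response, design: pd.DataFrame | None = None) -> list[int]:
    """Indices of OLS outliers: Cook's distance > 1 or |std. residual| > 3.

    Both thresholds are strict, so a point sitting exactly on a threshold
    is kept.  Intended to run before each mixed-effects analysis; the
    exclusion is per-analysis, not global.
    """
    y = np.asarray(response, dtype=float)
    if design is None:
        X = pd.DataFrame(index=range(len(y)))
    else:
        X = design.reset_index(drop=True).astype(float)
    Xc = sm.add_constant(X, has_constant="add")
    if len(y) <= Xc.shape[1]:
        raise ValueError(
            f"need more observations ({len(y)}) than regressors ({Xc.shape[1]})"
        )
    fit = sm.OLS(y, Xc).fit()
    influence = fit.get_influence()
    cooks = influence.cooks_distance[0]
    std_resid = influence.resid_studentized_internal
    flagged = np.flatnonzero((cooks > 1.0) | (np.abs(std_resid) > 3.0))
    return [int(i) for i in flagged]


@dataclass
class MixedModelResult:
    """Wave x drug random-intercept mixed model for one session measure."""

    interaction_estimate: float
    interaction_se: float
    interaction_p: float
    table: pd.DataFrame
    used_ols_fallback: bool


def wave_drug_mixed_model(data: pd.DataFrame,
                          value_col: str = "value") -> MixedModelResult:
    """Fit ``value ~ wave * drug + (1 | participant)``.

    ``data`` needs columns ``participant``, ``wave`` (baseline/followup),
    ``drug`` (placebo/citalopram) and the measure column.  Without any
    repeated participants the model degenerates to OLS (with a warning).
    """
    df = data.copy()
    df["wave_f"] = (df["wave"] == "followup").astype(float)
    df["drug_f"] = (df["drug"] == "citalopram").astype(float)
    df["y"] = df[value_col].astype(float)
    term = "wave_f:drug_f"
    repeated = df.groupby("participant").size().max() > 1
    if not repeated:
        warnings.warn(
            "no repeated participants: falling back to OLS for wave x drug",
            stacklevel=2,
        )
        fit = smf.ols("y ~ wave_f * drug_f", data=df).fit()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # singular random-effects fits
            fit = smf.mixedlm(
                "y ~ wave_f * drug_f", data=df, groups=df["participant"]
            ).fit(reml=True)
    table = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "pvalue": fit.pvalues}
    )
    return MixedModelResult(
        interaction_estimate=float(fit.params[term]),
        interaction_se=float(fit.bse[term]),
        interaction_p=float(fit.pvalues[term]),
        table=table,
        used_ols_fallback=not repeated,
    )
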