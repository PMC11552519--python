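"""Synthetic cohorts with the two-wave placebo/citalopram study design.

The generator emulates the study's structure — ~74 participants
randomised ~1:1 to citalopram vs. placebo, tested at baseline and about a
week later (a minority dropping out before follow-up), each session being
four dictator blocks (two 80%-fair, two 20%-fair dictators, apparent
ethnicity balanced) of 12 trials — with reports generated from the
classify-refine model at population-sampled parameter values.

Population parameters are Normal in transformed space; the drug effect
enters as additive transformed-space shifts at follow-up in the
citalopram arm (defaults: typing confidence down, prior self-interest
up).  The same machinery runs parameter-recovery and model-recovery
experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from classify_refine.agent_models import (
    PARAM_NAMES,
    AgentParams,
    carry_over,
    init_beliefs,
    marginal_attributions,
    predict_fair,
    update_beliefs,
)
from classify_refine.inference import (
    FitConfig,
    map_fit,
    transform_value,
    untransform_value,
)
from classify_refine.model_space import ModelSpec, get_model, information_criteria
from classify_refine.response_models import (
    DEFAULT_SCALE,
    ReportScale,
    apply_poc_bias,
    report_distribution,
)
from classify_refine.task_core import (
    DictatorBlock,
    Session,
    SplitOutcome,
    Trial,
    simulate_environment,
)

__all__ = [
    "PopulationConfig",
    "sample_population_params",
    "simulate_cohort",
    "simulate_session",
    "parameter_recovery",
    "model_recovery",
    "recovery_experiment",
]

#: Population means in transformed space (logit / log / identity), chosen
#: so that simulated behaviour is non-degenerate: moderate pessimism about
#: harm, mild expectation of self-interest, informative but refinable
#: typing confidence, and report noise that leaves reports clearly
#: correlated with model values.
DEFAULT_MEANS = {
    "pHI0": transform_value("pHI0", 0.30),
    "pSI0": transform_value("pSI0", 0.60),
    "dEv": np.log(2.0),
    "EvRat": 0.0,
    "alphaPrec": np.log(20.0),
    "wH": 2.0,
    "wS": 1.5,
    "w0": 1.0,
    "lambda_other": 0.0,
    "aEv": np.log(2.5),
    "omega": transform_value("omega", 0.60),
    "POCbias": 0.0,
}

#: Transformed-space population spreads.  EvRat and POCbias have zero
#: spread at their winning-model values; the rest give clear individual
#: differences without degenerate behaviour.
DEFAULT_SPREADS = {
    "pHI0": 0.7,
    "pSI0": 0.7,
    "dEv": 0.5,
    "EvRat": 0.0,
    "alphaPrec": 0.4,
    "wH": 0.7,
    "wS": 0.7,
    "w0": 0.7,
    "lambda_other": 0.8,
    "aEv": 1.0,
    "omega": 1.2,
    "POCbias": 0.0,
}

#: Additive transformed-space shifts applied at follow-up in the drug arm:
#: citalopram lowers typing confidence (log aEv) and raises the prior
#: self-interest tendency (logit pSI0).
DEFAULT_DRUG_DELTAS = {"aEv": -1.18, "pSI0": 1.32}


@dataclass(frozen=True)
class PopulationConfig:
    """Study-design and population-distribution settings for one cohort."""

    n_participants: int = 74
    proportion_drug: float = 42 / 74
    n_followup: int = 66
    waves: tuple[str, ...] = ("baseline", "followup")
    means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    spreads: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPREADS))
    drug_deltas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRUG_DELTAS))
    wave_deltas: dict[str, float] = field(default_factory=dict)
    outlier_fraction: float = 0.0
    outlier_scale: float = 4.0
    kind: str = "classify_refine"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion_drug <= 1.0):
            raise ValueError("proportion_drug must lie in [0, 1]")
        for name, v in self.spreads.items():
            if v < 0:
                raise ValueError(f"spread for {name} must be >= 0")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must lie in [0, 1]")

    def with_(self, **updates) -> "PopulationConfig":
        return replace(self, **updates)


def _clip_native(name: str, value: float) -> float:
    if name in ("pHI0", "pSI0"):
        return min(max(value, 1e-4), 1.0 - 1e-4)
    if name in ("omega", "lambda_other"):
        return min(max(value, 1e-6), 1.0 - 1e-6)
    if name in ("dEv", "EvRat", "alphaPrec", "aEv"):
        return max(value, 1e-6)
    return value


def sample_population_params(config: PopulationConfig) -> pd.DataFrame:
    """One row per participant x wave: covariates plus native parameters.

    Parameter vectors are drawn per participant as independent Normals in
    transformed space (optionally contaminated with a wider-scaled
    outlier fraction), shifted by wave and wave x drug deltas at
    follow-up, then mapped back to native space.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    n_drug = int(round(config.proportion_drug * n))
    drug = np.array(["citalopram"] * n_drug + ["placebo"] * (n - n_drug))
    rng.shuffle(drug)
    gender = rng.choice(["female", "male"], size=n, p=[0.6, 0.4])
    sses = rng.integers(1, 11, size=n)
    completes = np.zeros(n, dtype=bool)
    completes[rng.choice(n, size=min(config.n_followup, n), replace=False)] = True

    base_z = {}
    for name in PARAM_NAMES:
        mu = config.means[name]
        sd = config.spreads[name]
        z = rng.normal(mu, sd, size=n) if sd > 0 else np.full(n, mu)
        if config.outlier_fraction > 0 and sd > 0:
            mask = rng.random(n) < config.outlier_fraction
            z[mask] = rng.normal(mu, sd * config.outlier_scale, size=mask.sum())
        base_z[name] = z

    rows = []
    for i in range(n):
        for wave in config.waves:
            if wave == "followup" and not completes[i]:
                continue
            row = {
                "participant_id": f"p{i + 1:03d}",
                "wave": wave,
                "drug_group": drug[i],
                "gender": gender[i],
                "sses": int(sses[i]),
            }
            for name in PARAM_NAMES:
                z = base_z[name][i]
                if wave == "followup":
                    z += config.wave_deltas.get(name, 0.0)
                    if drug[i] == "citalopram":
                        z += config.drug_deltas.get(name, 0.0)
                row[name] = _clip_native(name, untransform_value(name, z))
            rows.append(row)
    return pd.DataFrame(rows)


def _block_design(rng: np.random.Generator) -> list[tuple[float, str]]:
    """Randomised order of (fairness_level, ethnicity), balanced 2x2."""
    design = [(0.8, "white"), (0.8, "nonwhite"), (0.2, "white"), (0.2, "nonwhite")]
    order = rng.permutation(4)
    return [design[i] for i in order]


def _draw_report(value: float, alpha_prec: float, scale: ReportScale,
                 rng: np.random.Generator) -> float:
    p = report_distribution(value, alpha_prec, scale)
    return float(scale.bin_values[rng.choice(len(p), p=p)])


def simulate_session(params: AgentParams, participant_id: str, wave: str,
                     drug_group: str, gender: str, sses: float,
                     rng: np.random.Generator, kind: str = "classify_refine",
                     scale: ReportScale = DEFAULT_SCALE) -> Session:
    """Forward-simulate one session: outcomes, agent beliefs, noisy reports."""
    blocks = []
    end_belief = None
    for b_pos, (fairness, ethnicity) in enumerate(_block_design(rng), start=1):
        fresh = init_beliefs(params, kind)
        belief = fresh if end_belief is None else carry_over(end_belief, params, fresh)
        outcomes = simulate_environment(fairness, 12, rng)
        nonwhite = ethnicity == "nonwhite"
        trials = []
        for t_idx, outcome in enumerate(outcomes, start=1):
            exp_rep = _draw_report(predict_fair(belief), params.alphaPrec, scale, rng)
            belief = update_beliefs(belief, outcome, params)
            hi_v, si_v = marginal_attributions(belief)
            hi_rep = _draw_report(
                apply_poc_bias(hi_v, params.POCbias, nonwhite),
                params.alphaPrec, scale, rng,
            )
            si_rep = _draw_report(
                apply_poc_bias(si_v, params.POCbias, nonwhite),
                params.alphaPrec, scale, rng,
            )
            trials.append(
                Trial(
                    trial_index=t_idx,
                    outcome=outcome,
                    expectation_report=exp_rep,
                    hi_report=hi_rep,
                    si_report=si_rep,
                    question_order="HI_first" if rng.random() < 0.5 else "SI_first",
                )
            )
        blocks.append(
            DictatorBlock(
                dictator_id=f"{participant_id}-{wave}-d{b_pos}",
                fairness_level=fairness,
                ethnicity=ethnicity,
                trials=tuple(trials),
            )
        )
        end_belief = belief
    return Session(
        participant_id=participant_id, wave=wave, drug_group=drug_group,
        gender=gender, sses=sses, blocks=tuple(blocks),
    )


def simulate_cohort(param_table: pd.DataFrame,
                    config: PopulationConfig) -> list[Session]:
    """Simulate a full cohort from a parameter table; fully seeded."""
    rng = np.random.default_rng(config.seed + 1)
    sessions = []
    for row in param_table.itertuples():
        params = AgentParams(**{n: getattr(row, n) for n in PARAM_NAMES})
        sessions.append(
            simulate_session(
                params, str(row.participant_id), str(row.wave),
                str(row.drug_group), str(row.gender), float(row.sses),
                rng, kind=config.kind,
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------

def _fit_cohort(sessions: list[Session], spec: ModelSpec,
                fit_config: FitConfig) -> dict[str, object]:
    fits = {}
    for i, s in enumerate(sessions):
        cfg = replace(fit_config, seed=fit_config.seed + i)
        fits[f"{s.participant_id}/{s.wave}"] = map_fit(s, spec, cfg)
    return fits


def parameter_recovery(config: PopulationConfig, fit_config: FitConfig,
                       spec: ModelSpec | None = None) -> pd.DataFrame:
    """Simulate a cohort, fit it, and score recovery per parameter.

    Returns one row per free parameter with non-zero generating spread:
    Pearson r, mean bias and RMSE of recovered minus generating values in
    transformed space.  Unconverged fits are flagged, not dropped.
    """
    spec = spec or get_model("winning")
    table = sample_population_params(config)
    sessions = simulate_cohort(table, config)
    fits = _fit_cohort(sessions, spec, fit_config)

    rows = []
    keys = [f"{r.participant_id}/{r.wave}" for r in table.itertuples()]
    for name in sorted(spec.free_params):
        if config.spreads.get(name, 0.0) <= 0.0:
            continue
        gen = np.array([transform_value(name, v) for v in table[name]])
        rec = np.array(
            [transform_value(name, getattr(fits[k].map_params, name)) for k in keys]
        )
        err = rec - gen
        r = float(np.corrcoef(gen, rec)[0, 1]) if np.std(rec) > 0 else 0.0
        rows.append(
            {
                "parameter": name,
                "r": r,
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err ** 2).mean())),
                "n": len(gen),
                "n_unconverged": int(sum(not fits[k].converged for k in keys)),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def model_recovery(n_replicates: int, n_agents: int, fit_config: FitConfig,
                   base_config: PopulationConfig | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Generate cohorts from each family, fit both, BIC-select per cohort.

    For every replicate and each generating family (classify-refine and
    classic) a single-wave cohort of ``n_agents`` is simulated and fitted
    with both the winning classify-refine model and the classic model;
    the family with the lower median BIC is selected.  Returns one row
    per replicate x generating family.
    """
    base = base_config or PopulationConfig()
    spec_cr = get_model("winning")
    spec_classic = get_model("classic-full")
    rows = []
    for rep in range(n_replicates):
        for gen_kind, gen_name in (("classify_refine", "classify-refine"),
                                   ("classic", "classic")):
            cfg = base.with_(
                n_participants=n_agents, n_followup=0, waves=("baseline",),
                kind=gen_kind, seed=seed + 1000 * rep + (0 if gen_kind == "classic" else 500),
            )
            table = sample_population_params(cfg)
            sessions = simulate_cohort(table, cfg)
            fcfg = replace(fit_config, seed=fit_config.seed + rep)
            medians = {}
            for spec in (spec_cr, spec_classic):
                fits = _fit_cohort(sessions, spec, fcfg)
                bics = [
                    information_criteria(f, spec, n_participants=len(fits))[0]
                    for f in fits.values()
                ]
                medians[spec.name] = float(np.median(bics))
            selected = (
                "classify-refine"
                if medians["winning"] < medians["classic-full"]
                else "classic"
            )
            rows.append(
                {
                    "replicate": rep,
                    "generating": gen_name,
                    "median_bic_classify_refine": medians["winning"],
                    "median_bic_classic": medians["classic-full"],
                    "selected": selected,
                    "correct": selected == gen_name,
                }
            )
    return pd.DataFrame(rows)


def recovery_experiment(config: PopulationConfig, fit_config: FitConfig,
                        n_model_replicates: int = 5, n_model_agents: int = 12,
                        out_dir: str | Path | None = None) -> dict:
    """Parameter- and model-recovery report; optionally written to disk."""
    param_df = parameter_recovery(config, fit_config)
    model_df = model_recovery(
        n_model_replicates, n_model_agents, fit_config,
        base_config=config, seed=config.seed + 7,
    )
    confusion = (
        model_df.groupby("generating")["correct"].mean().to_dict()
        if len(model_df) else {}
    )
    report = {
        "parameter_recovery": param_df,
        "model_recovery": model_df,
        "model_recovery_accuracy": confusion,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        param_df.to_csv(out / "parameter_recovery.csv")
        model_df.to_csv(out / "model_recovery.csv", index=False)
        summary = {
            "parameter_recovery_r": param_df["r"].to_dict(),
            "model_recovery_accuracy": confusion,
        }
        (out / "recovery_summary.json").write_text(json.dumps(summary, indent=2))
    return report
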