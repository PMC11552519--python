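"""Domain types and CSV I/O for the Sharing Game task.

The Sharing Game is an iterated Dictator task: each participant-session
consists of four dictator blocks of 12 consecutive trials.  On every trial
the dictator splits 10 pence either fairly (5:5) or unfairly (10:0); the
participant first reports their expectation that the split will be fair,
observes the split, then reports graded attributions of harmful intent
(HI) and self-interest (SI).  Two dictators split fairly 80% of the time
and two 20% of the time; dictator photographs carry an apparent-ethnicity
label (white vs. nonwhite) used by the person-of-colour bias model.

All probability reports are stored internally on [0, 1]; the on-screen
scale of a data file (0-1, 0-10, 0-100, ...) is declared via
:class:`SchemaConfig`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SplitOutcome",
    "Trial",
    "DictatorBlock",
    "Session",
    "SchemaConfig",
    "SchemaError",
    "StructureError",
    "TaskValidationError",
    "read_sessions",
    "write_sessions",
    "simulate_environment",
    "TRIALS_PER_BLOCK",
    "BLOCKS_PER_SESSION",
    "CSV_COLUMNS",
]

TRIALS_PER_BLOCK = 12
BLOCKS_PER_SESSION = 4
FAIRNESS_LEVELS = (0.8, 0.2)
ETHNICITY_LABELS = ("white", "nonwhite")

CSV_COLUMNS = [
    "participant_id",
    "wave",
    "drug_group",
    "gender",
    "sses",
    "block_position",
    "dictator_id",
    "fairness_level",
    "ethnicity",
    "trial_index",
    "outcome",
    "expectation_report",
    "hi_report",
    "si_report",
    "question_order",
]


class SchemaError(ValueError):
    """A required column is missing or the schema declaration is invalid."""


class TaskValidationError(ValueError):
    """A field value violates its declared range or category."""


class StructureError(ValueError):
    """Block/session structure violates the task design."""


class SplitOutcome(enum.Enum):
    """Dictator's split on one trial: fair (5:5) or unfair (10:0)."""

    FAIR = "fair"
    UNFAIR = "unfair"

    @property
    def is_fair(self) -> bool:
        return self is SplitOutcome.FAIR


@dataclass(frozen=True)
class Trial:
    """One trial: the observed split plus the three probability reports.

    ``expectation_report`` is collected before the split is shown;
    ``hi_report`` and ``si_report`` afterwards, in randomised order
    recorded by ``question_order``.
    """

    trial_index: int
    outcome: SplitOutcome
    expectation_report: float
    hi_report: float
    si_report: float
    question_order: str = "HI_first"

    def __post_init__(self) -> None:
        for name in ("expectation_report", "hi_report", "si_report"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise TaskValidationError(
                    f"{name}={v!r} outside [0, 1] on trial {self.trial_index}"
                )
        if self.question_order not in ("HI_first", "SI_first"):
            raise TaskValidationError(
                f"question_order must be 'HI_first' or 'SI_first', "
                f"got {self.question_order!r}"
            )


@dataclass(frozen=True)
class DictatorBlock:
    """Twelve consecutive trials with one dictator of known fairness level."""

    dictator_id: str
    fairness_level: float
    ethnicity: str
    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        if self.fairness_level not in FAIRNESS_LEVELS:
            raise TaskValidationError(
                f"fairness_level must be one of {FAIRNESS_LEVELS}, "
                f"got {self.fairness_level}"
            )
        if self.ethnicity not in ETHNICITY_LABELS:
            raise TaskValidationError(
                f"ethnicity must be one of {ETHNICITY_LABELS}, "
                f"got {self.ethnicity!r}"
            )
        object.__setattr__(self, "trials", tuple(self.trials))
        if len(self.trials) != TRIALS_PER_BLOCK:
            raise StructureError(
                f"block {self.dictator_id!r} has {len(self.trials)} trials, "
                f"expected {TRIALS_PER_BLOCK}"
            )
        indices = [t.trial_index for t in self.trials]
        if indices != list(range(1, TRIALS_PER_BLOCK + 1)):
            raise StructureError(
                f"block {self.dictator_id!r} trial indices {indices} are not "
                f"consecutive 1..{TRIALS_PER_BLOCK}"
            )

    @property
    def is_nonwhite(self) -> bool:
        return self.ethnicity == "nonwhite"


@dataclass(frozen=True)
class Session:
    """One participant x wave: four dictator blocks in presentation order.

    Block order is preserved because carry-over learning from one dictator
    to the next depends on it.
    """

    participant_id: str
    wave: str
    drug_group: str
    gender: str
    sses: float
    blocks: tuple[DictatorBlock, ...]

    def __post_init__(self) -> None:
        if self.wave not in ("baseline", "followup"):
            raise TaskValidationError(
                f"wave must be 'baseline' or 'followup', got {self.wave!r}"
            )
        if self.drug_group not in ("placebo", "citalopram"):
            raise TaskValidationError(
                f"drug_group must be 'placebo' or 'citalopram', "
                f"got {self.drug_group!r}"
            )
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if len(self.blocks) != BLOCKS_PER_SESSION:
            raise StructureError(
                f"session {self.participant_id}/{self.wave} has "
                f"{len(self.blocks)} blocks, expected {BLOCKS_PER_SESSION}"
            )
        levels = sorted(b.fairness_level for b in self.blocks)
        if levels != [0.2, 0.2, 0.8, 0.8]:
            raise StructureError(
                f"session {self.participant_id}/{self.wave} must have exactly "
                f"two blocks at each fairness level, got {levels}"
            )

    @property
    def n_trials(self) -> int:
        return sum(len(b.trials) for b in self.blocks)


@dataclass(frozen=True)
class SchemaConfig:
    """How to interpret a sessions CSV.

    Parameters
    ----------
    report_scale
        Maximum of the on-file report scale; reports are divided by this
        on read and multiplied on write (1 leaves them unchanged, 100
        rescales percentage responses onto [0, 1]).
    aliases
        Mapping from canonical column name to the name used in the file.
    """

    report_scale: float = 1.0
    aliases: dict[str, str] = field(default_factory=dict)

    def column(self, canonical: str) -> str:
        return self.aliases.get(canonical, canonical)


_REPORT_COLUMNS = ("expectation_report", "hi_report", "si_report")


def read_sessions(path, schema_config: SchemaConfig | None = None) -> list[Session]:
    """Read validated Sessions from a long-format CSV (one row per trial).

    Row order within a participant/wave defines block and trial order.
    Reports are rescaled onto [0, 1] according to
    ``schema_config.report_scale``.
    """
    schema = schema_config or SchemaConfig()
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if schema.column(c) not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s): {', '.join(schema.column(c) for c in missing)}"
        )
    df = df.rename(columns={schema.column(c): c for c in CSV_COLUMNS})

    for col in _REPORT_COLUMNS:
        raw = df[col].astype(float)
        bad = raw.index[(raw < 0) | (raw > schema.report_scale) | raw.isna()]
        if len(bad):
            row = int(bad[0]) + 2  # 1-based, counting the header row
            raise TaskValidationError(
                f"column {col!r} outside [0, {schema.report_scale}] at "
                f"file row {row}"
            )
        df[col] = raw / schema.report_scale

    sessions: list[Session] = []
    for (pid, wave), sdf in df.groupby(["participant_id", "wave"], sort=False):
        blocks = []
        for _, bdf in sdf.groupby("block_position", sort=True):
            trials = tuple(
                Trial(
                    trial_index=int(r.trial_index),
                    outcome=SplitOutcome(r.outcome),
                    expectation_report=float(r.expectation_report),
                    hi_report=float(r.hi_report),
                    si_report=float(r.si_report),
                    question_order=str(r.question_order),
                )
                for r in bdf.itertuples()
            )
            blocks.append(
                DictatorBlock(
                    dictator_id=str(bdf["dictator_id"].iloc[0]),
                    fairness_level=float(bdf["fairness_level"].iloc[0]),
                    ethnicity=str(bdf["ethnicity"].iloc[0]),
                    trials=trials,
                )
            )
        first = sdf.iloc[0]
        sessions.append(
            Session(
                participant_id=str(pid),
                wave=str(wave),
                drug_group=str(first["drug_group"]),
                gender=str(first["gender"]),
                sses=float(first["sses"]),
                blocks=tuple(blocks),
            )
        )
    return sessions


def sessions_to_frame(sessions: list[Session], report_scale: float = 1.0) -> pd.DataFrame:
    """Long-format DataFrame with one row per trial, stable column order."""
    rows = []
    for s in sessions:
        for b_pos, block in enumerate(s.blocks, start=1):
            for t in block.trials:
                rows.append(
                    {
                        "participant_id": s.participant_id,
                        "wave": s.wave,
                        "drug_group": s.drug_group,
                        "gender": s.gender,
                        "sses": s.sses,
                        "block_position": b_pos,
                        "dictator_id": block.dictator_id,
                        "fairness_level": block.fairness_level,
                        "ethnicity": block.ethnicity,
                        "trial_index": t.trial_index,
                        "outcome": t.outcome.value,
                        "expectation_report": t.expectation_report * report_scale,
                        "hi_report": t.hi_report * report_scale,
                        "si_report": t.si_report * report_scale,
                        "question_order": t.question_order,
                    }
                )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_sessions(sessions: list[Session], path,
                   schema_config: SchemaConfig | None = None) -> None:
    """Write Sessions as long-format CSV; inverse of :func:`read_sessions`."""
    scale = (schema_config or SchemaConfig()).report_scale
    sessions_to_frame(sessions, report_scale=scale).to_csv(path, index=False)


def simulate_environment(fairness_level: float, n_trials: int,
                         seed: int | np.random.Generator) -> list[SplitOutcome]:
    """I.i.d. Bernoulli(fairness_level) split outcomes for one dictator."""
    if not (0.0 <= fairness_level <= 1.0):
        raise TaskValidationError(
            f"fairness_level must be a probability, got {fairness_level}"
        )
    if n_trials < 1:
        raise TaskValidationError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    draws = rng.random(n_trials) < fairness_level
    return [SplitOutcome.FAIR if d else SplitOutcome.UNFAIR for d in draws]


def replace_trials(block: DictatorBlock, trials) -> DictatorBlock:
    """Copy a block with new trials (convenience for simulators/tests)."""
    return replace(block, trials=tuple(trials))
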