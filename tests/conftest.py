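import numpy as np
import pytest

from classify_refine.agent_models import AgentParams
from classify_refine.task_core import DictatorBlock, Session, SplitOutcome, Trial


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def params():
    """A mid-range, non-degenerate parameter setting."""
    return AgentParams(
        pHI0=0.3, pSI0=0.6, dEv=2.0, EvRat=1.0, alphaPrec=6.0,
        wH=2.0, wS=1.5, w0=1.0, lambda_other=0.5, aEv=3.0, omega=0.85,
        POCbias=0.0,
    )


def make_trial(i, outcome=SplitOutcome.FAIR, exp=0.5, hi=0.5, si=0.5,
               order="HI_first"):
    return Trial(trial_index=i, outcome=outcome, expectation_report=exp,
                 hi_report=hi, si_report=si, question_order=order)


def make_block(dictator_id="d1", fairness=0.8, ethnicity="white",
               outcomes=None, reports=None):
    """12-trial block; ``outcomes`` is an iterable of booleans (fair?)."""
    if outcomes is None:
        outcomes = [True] * 12
    trials = []
    for i, fair in enumerate(outcomes, start=1):
        exp, hi, si = (0.5, 0.5, 0.5) if reports is None else reports[i - 1]
        trials.append(
            make_trial(i, SplitOutcome.FAIR if fair else SplitOutcome.UNFAIR,
                       exp, hi, si)
        )
    return DictatorBlock(dictator_id=dictator_id, fairness_level=fairness,
                         ethnicity=ethnicity, trials=tuple(trials))


def make_session(participant_id="p001", wave="baseline", drug="placebo",
                 blocks=None, outcomes_per_block=None):
    if blocks is None:
        if outcomes_per_block is None:
            rng = np.random.default_rng(7)
            outcomes_per_block = [
                list(rng.random(12) < f) for f in (0.8, 0.2, 0.8, 0.2)
            ]
        fairness = (0.8, 0.2, 0.8, 0.2)
        eth = ("white", "nonwhite", "nonwhite", "white")
        blocks = tuple(
            make_block(f"d{j + 1}", fairness[j], eth[j], outcomes_per_block[j])
            for j in range(4)
        )
    return Session(participant_id=participant_id, wave=wave, drug_group=drug,
                   gender="female", sses=5.0, blocks=tuple(blocks))


@pytest.fixture
def session():
    return make_session()
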