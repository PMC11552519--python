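"""Learning-core tests, anchored on an independent enumeration oracle.

The oracle re-derives the trial-by-trial update (Bayes step,
posterior-weighted credit, forgetting, carry-over) with plain dicts and
scalar arithmetic, independently of the package's array implementation.
"""

import itertools
import math

import numpy as np
import pytest

from classify_refine.agent_models import (
    AgentParams,
    carry_over,
    init_beliefs,
    marginal_attributions,
    policy_fair_prob,
    predict_fair,
    update_beliefs,
)
from classify_refine.task_core import SplitOutcome

FAIR, UNFAIR = SplitOutcome.FAIR, SplitOutcome.UNFAIR


# ---------------------------------------------------------------------------
# Independent oracle: dict-based, scalar arithmetic
# ---------------------------------------------------------------------------

def _sigma(z):
    return 1.0 / (1.0 + math.exp(-z))


def oracle_trajectory(p: AgentParams, outcome_blocks):
    """Trial-by-trial (predictive, posterior, hi, si) for the 2x2 learner.

    ``outcome_blocks`` is a list of blocks, each a list of booleans
    (True = fair).  Carry-over is applied between blocks.
    """
    levels = [0.05, 0.95]
    states = [(h, s) for h in levels for s in levels]
    pol = {st: _sigma(p.w0 - p.wH * st[0] - p.wS * st[1]) for st in states}
    base = {st: (p.aEv * pol[st], p.aEv * (1.0 - pol[st])) for st in states}
    prior0 = {
        (h, s): (p.pHI0 if h == 0.95 else 1.0 - p.pHI0)
        * (p.pSI0 if s == 0.95 else 1.0 - p.pSI0)
        for (h, s) in states
    }

    records = []
    counts = {st: base[st] for st in states}
    for b, block in enumerate(outcome_blocks):
        if b > 0:
            counts = {
                st: (
                    base[st][0] + p.lambda_other * (counts[st][0] - base[st][0]),
                    base[st][1] + p.lambda_other * (counts[st][1] - base[st][1]),
                )
                for st in states
            }
        else:
            counts = {st: base[st] for st in states}
        belief = dict(prior0)
        for fair in block:
            phat = {st: counts[st][0] / (counts[st][0] + counts[st][1])
                    for st in states}
            pred = sum(belief[st] * phat[st] for st in states)
            unnorm = {
                st: belief[st] * (phat[st] if fair else 1.0 - phat[st])
                for st in states
            }
            z = sum(unnorm.values())
            post = {st: v / z for st, v in unnorm.items()}
            hi = sum(v for (h, s), v in post.items() if h == 0.95)
            si = sum(v for (h, s), v in post.items() if s == 0.95)
            new_counts = {}
            for st in states:
                cf, cu = counts[st]
                if fair:
                    cf += post[st]
                else:
                    cu += post[st]
                new_counts[st] = (
                    base[st][0] + p.omega * (cf - base[st][0]),
                    base[st][1] + p.omega * (cu - base[st][1]),
                )
            counts = new_counts
            belief = post
            records.append((pred, [post[st] for st in states], hi, si))
    return records


def run_package_trajectory(p: AgentParams, outcome_blocks):
    records = []
    end = None
    for block in outcome_blocks:
        fresh = init_beliefs(p)
        belief = fresh if end is None else carry_over(end, p, fresh)
        for fair in block:
            pred = predict_fair(belief)
            belief = update_beliefs(belief, FAIR if fair else UNFAIR, p)
            hi, si = marginal_attributions(belief)
            records.append((pred, list(belief.state_posterior), hi, si))
        end = belief
    return records


# ---------------------------------------------------------------------------
# Policy function
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "hi,si,w0,wH,wS,expected",
    [
        (0.0, 0.0, 0.0, 1.0, 1.0, 0.5),
        (0.95, 0.05, 2.0, 4.0, 1.0, _sigma(-1.85)),
        (0.3, 0.7, 3.0, 0.0, 0.0, _sigma(3.0)),
    ],
)
def test_policy_fair_prob_logistic(hi, si, w0, wH, wS, expected):
    assert policy_fair_prob(hi, si, w0, wH, wS) == pytest.approx(expected, abs=1e-12)


def test_policy_monotone_in_harm_and_selfishness():
    base = policy_fair_prob(0.2, 0.2, 1.0, 2.0, 1.5)
    assert policy_fair_prob(0.8, 0.2, 1.0, 2.0, 1.5) < base
    assert policy_fair_prob(0.2, 0.8, 1.0, 2.0, 1.5) < base


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

class TestInitBeliefs:
    def test_symmetric_prior_is_uniform(self, params):
        b = init_beliefs(params.replace(pHI0=0.5, pSI0=0.5))
        assert np.allclose(b.state_prior, 0.25)

    def test_joint_prior_is_product_of_marginals(self, params):
        b = init_beliefs(params.replace(pHI0=0.9, pSI0=0.5))
        # HI-major order: index 3 = (highHI, highSI)
        assert b.state_prior[3] == pytest.approx(0.45)
        hi_mass = b.state_prior[2] + b.state_prior[3]
        assert hi_mass == pytest.approx(0.9)

    def test_counts_split_policy_mass(self, params):
        p = params.replace(aEv=10.0, wH=1e-9, wS=1e-9,
                           w0=math.log(0.8 / 0.2))
        b = init_beliefs(p)
        assert np.allclose(b.likelihood.counts[:, 0], 8.0, atol=1e-6)
        assert np.allclose(b.likelihood.counts[:, 1], 2.0, atol=1e-6)

    def test_classic_grid_is_fixed_six_bins(self, params):
        b = init_beliefs(params, kind="classic")
        assert b.grid.n_states == 36
        assert b.grid.hi_values == tuple((2 * j + 1) / 12 for j in range(6))
        assert b.likelihood.fixed_fair_prob is not None


# ---------------------------------------------------------------------------
# Update mechanics
# ---------------------------------------------------------------------------

class TestUpdate:
    def test_bayes_step_hand_computed(self, params):
        # engineer p_hat(fair) = (0.9, 0.1, 0.9, 0.1) via direct counts
        b = init_beliefs(params.replace(pHI0=0.5, pSI0=0.5))
        counts = np.array([[9.0, 1.0], [1.0, 9.0], [9.0, 1.0], [1.0, 9.0]])
        b = type(b)(grid=b.grid, state_prior=b.state_prior,
                    state_posterior=b.state_posterior,
                    likelihood=type(b.likelihood)(counts, counts.copy()))
        out = update_beliefs(b, FAIR, params.replace(omega=1.0))
        assert np.allclose(out.state_posterior, [0.45, 0.05, 0.45, 0.05])

    def test_unit_credit_without_forgetting(self, params):
        p = params.replace(omega=1.0)
        b = init_beliefs(p)
        before = b.likelihood.counts.copy()
        out = update_beliefs(b, FAIR, p)
        gained = out.likelihood.counts[:, 0] - before[:, 0]
        assert np.allclose(gained, out.state_posterior)
        assert np.allclose(out.likelihood.counts[:, 1], before[:, 1])

    def test_forgetting_decays_halfway(self, params):
        # counts 14 vs baseline 10 with omega=0.5 -> 12 after decay
        base = 10.0
        assert base + 0.5 * (14.0 - base) == 12.0
        p = params.replace(omega=0.0)
        b = init_beliefs(p)
        out = update_beliefs(b, FAIR, p)
        # total forgetting: counts return exactly to baseline
        assert np.allclose(out.likelihood.counts, b.likelihood.baseline_counts)

    def test_posterior_normalised_after_every_trial(self, params):
        b = init_beliefs(params)
        for fair in [True, False, False, True, True]:
            b = update_beliefs(b, FAIR if fair else UNFAIR, params)
            assert abs(b.state_posterior.sum() - 1.0) < 1e-12

    def test_fair_observation_raises_credited_fair_prob(self, params):
        p = params.replace(omega=1.0)
        b = init_beliefs(p)
        before = b.likelihood.fair_prob().copy()
        out = update_beliefs(b, FAIR, p)
        after = out.likelihood.fair_prob()
        credited = out.state_posterior > 0
        assert np.all(after[credited] > before[credited])


# ---------------------------------------------------------------------------
# Oracle equivalence
# ---------------------------------------------------------------------------

PARAM_SETTINGS = [
    dict(pHI0=0.3, pSI0=0.6, dEv=2.0, EvRat=1.0, alphaPrec=6.0, wH=2.0,
         wS=1.5, w0=1.0, lambda_other=0.5, aEv=3.0, omega=0.85, POCbias=0.0),
    dict(pHI0=0.7, pSI0=0.2, dEv=1.0, EvRat=2.0, alphaPrec=3.0, wH=0.5,
         wS=3.0, w0=-0.5, lambda_other=0.9, aEv=0.7, omega=0.5, POCbias=0.3),
    dict(pHI0=0.5, pSI0=0.5, dEv=4.0, EvRat=0.5, alphaPrec=10.0, wH=4.0,
         wS=0.2, w0=2.0, lambda_other=0.1, aEv=10.0, omega=1.0, POCbias=0.0),
]


@pytest.mark.parametrize("setting", PARAM_SETTINGS)
def test_oracle_equivalence_all_single_block_sequences(setting):
    """Every 4-trial outcome sequence matches the enumeration oracle."""
    p = AgentParams(**setting)
    for seq in itertools.product([True, False], repeat=4):
        expected = oracle_trajectory(p, [list(seq)])
        got = run_package_trajectory(p, [list(seq)])
        for (pred_e, post_e, hi_e, si_e), (pred_g, post_g, hi_g, si_g) in zip(
            expected, got
        ):
            assert pred_g == pytest.approx(pred_e, abs=1e-10)
            assert np.allclose(post_g, post_e, atol=1e-10)
            assert hi_g == pytest.approx(hi_e, abs=1e-10)
            assert si_g == pytest.approx(si_e, abs=1e-10)


@pytest.mark.parametrize("setting", PARAM_SETTINGS)
def test_oracle_equivalence_across_blocks_with_carry_over(setting):
    p = AgentParams(**setting)
    blocks = [[True, True, False], [False, False, True], [True, False, True]]
    expected = oracle_trajectory(p, blocks)
    got = run_package_trajectory(p, blocks)
    for e, g in zip(expected, got):
        assert np.allclose(g[1], e[1], atol=1e-10)
        assert g[0] == pytest.approx(e[0], abs=1e-10)


# ---------------------------------------------------------------------------
# Attributions and carry-over
# ---------------------------------------------------------------------------

class TestMarginals:
    def test_point_mass_posterior(self, params):
        b = init_beliefs(params)
        post = np.array([0.0, 0.0, 1.0, 0.0])  # (highHI, lowSI)
        b = type(b)(grid=b.grid, state_prior=post, state_posterior=post,
                    likelihood=b.likelihood)
        assert marginal_attributions(b) == (1.0, 0.0)

    def test_uniform_posterior_gives_half(self, params):
        b = init_beliefs(params.replace(pHI0=0.5, pSI0=0.5))
        assert marginal_attributions(b) == pytest.approx((0.5, 0.5))

    def test_classic_uniform_grid_mean(self, params):
        b = init_beliefs(params.replace(pHI0=0.5, pSI0=0.5, dEv=2.0),
                         kind="classic")
        uniform = np.full(36, 1.0 / 36)
        b = type(b)(grid=b.grid, state_prior=uniform, state_posterior=uniform,
                    likelihood=b.likelihood)
        hi, si = marginal_attributions(b)
        assert hi == pytest.approx(0.5) and si == pytest.approx(0.5)

    def test_classic_hi_non_increasing_after_fair(self, params):
        p = params.replace(wH=2.0, wS=1.0)
        b = init_beliefs(p, kind="classic")
        hi_before = float(np.dot(b.state_prior, b.grid.joint_hi()))
        b = update_beliefs(b, FAIR, p)
        hi_after, _ = marginal_attributions(b)
        assert hi_after <= hi_before + 1e-12


class TestCarryOver:
    def _learned(self, p):
        b = init_beliefs(p)
        for fair in [True, True, False, True]:
            b = update_beliefs(b, FAIR if fair else UNFAIR, p)
        return b

    def test_lambda_zero_resets(self, params):
        end = self._learned(params)
        fresh = init_beliefs(params)
        nxt = carry_over(end, params.replace(lambda_other=0.0), fresh)
        assert np.allclose(nxt.likelihood.counts, fresh.likelihood.counts)
        assert np.allclose(nxt.state_prior, fresh.state_prior)

    def test_lambda_one_carries_counts_fully(self, params):
        end = self._learned(params)
        fresh = init_beliefs(params)
        nxt = carry_over(end, params.replace(lambda_other=1.0), fresh)
        assert np.allclose(nxt.likelihood.counts, end.likelihood.counts)

    def test_lambda_half_interpolates(self, params):
        end = self._learned(params)
        fresh = init_beliefs(params)
        nxt = carry_over(end, params.replace(lambda_other=0.5), fresh)
        expected = fresh.likelihood.counts + 0.5 * (
            end.likelihood.counts - fresh.likelihood.counts
        )
        assert np.allclose(nxt.likelihood.counts, expected)


# ---------------------------------------------------------------------------
# Limits
# ---------------------------------------------------------------------------

def test_high_typing_confidence_freezes_likelihood(params):
    """aEv -> inf reduces to the fixed-likelihood 2x2 filter (tol 1e-4)."""
    p = params.replace(aEv=1e6)
    pol = {
        st: policy_fair_prob(st[0], st[1], p.w0, p.wH, p.wS)
        for st in [(0.05, 0.05), (0.05, 0.95), (0.95, 0.05), (0.95, 0.95)]
    }
    lik = np.array([pol[(0.05, 0.05)], pol[(0.05, 0.95)],
                    pol[(0.95, 0.05)], pol[(0.95, 0.95)]])
    prior = np.array(
        [(1 - p.pHI0) * (1 - p.pSI0), (1 - p.pHI0) * p.pSI0,
         p.pHI0 * (1 - p.pSI0), p.pHI0 * p.pSI0]
    )
    b = init_beliefs(p)
    seq = [True, False, True, True, False, True, True, True, False, True, True, False]
    belief_fixed = prior.copy()
    for fair in seq:
        pred_fixed = float(np.dot(belief_fixed, lik))
        assert predict_fair(b) == pytest.approx(pred_fixed, abs=1e-4)
        b = update_beliefs(b, FAIR if fair else UNFAIR, p)
        w = lik if fair else 1.0 - lik
        belief_fixed = belief_fixed * w
        belief_fixed /= belief_fixed.sum()
        assert np.allclose(b.state_posterior, belief_fixed, atol=1e-4)


def test_omega_one_lambda_zero_is_independent_block_learning(params):
    """With perfect retention and no carry-over, blocks are independent."""
    p = params.replace(omega=1.0, lambda_other=0.0)
    one_block = oracle_trajectory(p, [[True, False, True]])
    two_blocks = run_package_trajectory(
        p, [[False, True, False, False], [True, False, True]]
    )
    for e, g in zip(one_block, two_blocks[4:]):
        assert np.allclose(g[1], e[1], atol=1e-12)
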