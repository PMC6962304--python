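"""Softmax choice rule, delta-rule updates, likelihood, and agent simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mouseprl.models import (
    RLParams, ValueState, choice_probability, negative_log_likelihood,
    simulate_agent, update_values,
)
from mouseprl.task import (
    BACK, FRONT, OMIT, NoDataError, PhaseSpec, SubjectDataset, TrialRecord,
    days_to_criterion,
)
from mouseprl.cohort import POPULATION_ESTIMATES, fixed_block_schedule

from conftest import make_dataset


def single(alpha, beta):
    return RLParams("single", beta=beta, alpha=alpha)


PD = POPULATION_ESTIMATES  # persev_dual at published population values


class TestChoiceProbability:
    def test_symmetric_state_is_indifferent(self):
        st_ = ValueState(0.4, 0.4, 0, 0)
        for params in (single(0.1, 5.0), PD):
            assert choice_probability(st_, params) == pytest.approx(0.5)

    def test_perseveration_boost_at_equal_values(self):
        """With equal values, previous front choice and delta = 0.744, the
        repeat probability is expit(0.744) = 0.6779 for any beta."""
        for beta in (0.0, 3.275, 20.0):
            p = RLParams("persev_dual", beta=beta, alpha_pos=0.01,
                         alpha_neg=0.03, delta=0.744)
            got = choice_probability(ValueState(0.7, 0.7, 1, 0), p)
            assert got == pytest.approx(1 / (1 + math.exp(-0.744)), abs=1e-12)

    def test_zero_beta_zero_delta_ignores_values(self):
        p = RLParams("persev", beta=0.0, alpha=0.2, delta=0.0)
        assert choice_probability(ValueState(1.0, 0.0, 0, 1), p) == 0.5

    def test_extreme_logits_do_not_overflow(self):
        p = single(0.1, 50.0)
        hi = choice_probability(ValueState(1.0, 0.0, 0, 0), p)
        lo = choice_probability(ValueState(0.0, 1.0, 0, 0), p)
        assert 0.0 < lo < hi < 1.0

    @given(
        vf=st.floats(0, 1), vb=st.floats(0, 1),
        beta=st.floats(0, 50), delta=st.floats(-10, 10),
        prev=st.sampled_from([(0, 0), (1, 0), (0, 1)]),
    )
    def test_front_back_probabilities_sum_to_one(self, vf, vb, beta, delta, prev):
        p = RLParams("persev_dual", beta=beta, alpha_pos=0.1, alpha_neg=0.1,
                     delta=delta)
        p_f = choice_probability(ValueState(vf, vb, *prev), p)
        p_b = choice_probability(ValueState(vb, vf, prev[1], prev[0]), p)
        assert p_f + p_b == pytest.approx(1.0, abs=1e-12)


class TestUpdateValues:
    def test_zero_prediction_error_is_inert(self):
        out = update_values(ValueState(1.0, 1.0, 0, 0), FRONT, 1, single(0.7, 1))
        assert out.v_front == 1.0

    def test_negative_error_uses_negative_rate(self):
        p = RLParams("dual", beta=1.0, alpha_pos=0.9, alpha_neg=0.0282)
        out = update_values(ValueState(1.0, 1.0, 0, 0), FRONT, 0, p)
        assert out.v_front == pytest.approx(0.9718)
        assert out.v_back == 1.0

    def test_positive_error_uses_positive_rate(self):
        p = RLParams("dual", beta=1.0, alpha_pos=0.2, alpha_neg=0.9)
        out = update_values(ValueState(0.5, 0.5, 0, 0), FRONT, 1, p)
        assert out.v_front == pytest.approx(0.6)

    def test_indicators_follow_choice(self):
        out = update_values(ValueState(0.5, 0.5, 1, 0), BACK, 0, single(0.1, 1))
        assert (out.c_front, out.c_back) == (0, 1)

    def test_omission_rejected(self):
        with pytest.raises(ValueError):
            update_values(ValueState(), OMIT, 0, single(0.1, 1))

    @given(
        data=st.lists(st.tuples(st.sampled_from([FRONT, BACK]),
                                st.integers(0, 1)), max_size=40),
        a_pos=st.floats(0, 1), a_neg=st.floats(0, 1),
    )
    def test_values_stay_in_unit_interval(self, data, a_pos, a_neg):
        p = RLParams("dual", beta=1.0, alpha_pos=a_pos, alpha_neg=a_neg)
        state = ValueState()
        for choice, reward in data:
            state = update_values(state, choice, reward, p)
            assert 0.0 <= state.v_front <= 1.0
            assert 0.0 <= state.v_back <= 1.0


class TestRLParamsValidation:
    def test_variant_field_mismatch(self):
        with pytest.raises(ValueError):
            RLParams("single", beta=1.0, alpha_pos=0.1, alpha_neg=0.1)
        with pytest.raises(ValueError):
            RLParams("dual", beta=1.0, alpha=0.1)
        with pytest.raises(ValueError):
            RLParams("single", beta=1.0, alpha=0.1, delta=1.0)
        with pytest.raises(ValueError):
            RLParams("persev", beta=1.0, alpha=0.1)  # delta missing

    def test_range_checks(self):
        with pytest.raises(ValueError):
            single(1.5, 1.0)
        with pytest.raises(ValueError):
            single(0.5, -1.0)


def random_dataset(rng, n_sessions=10, session_length=100, omission_rate=0.05):
    """Arbitrary (non-model) choice/reward records for likelihood tests."""
    trials = []
    for s in range(n_sessions):
        for t in range(session_length):
            u = rng.random()
            if u < omission_rate:
                choice, rewarded = OMIT, False
            else:
                choice = FRONT if rng.random() < 0.5 else BACK
                rewarded = rng.random() < 0.5
            trials.append(TrialRecord("x", "p", s, t, choice, FRONT, rewarded))
    return SubjectDataset("x", trials)


class TestNegativeLogLikelihood:
    def test_single_indifferent_trial(self):
        ds = make_dataset([[FRONT]])
        assert negative_log_likelihood(ds, single(0.1, 0.0)) == pytest.approx(math.log(2))

    def test_indifferent_model_gives_n_log_two(self, rng):
        ds = random_dataset(rng, n_sessions=3)
        n = sum(not t.is_omission for t in ds.trials)
        p = RLParams("persev_dual", beta=0.0, alpha_pos=0.3, alpha_neg=0.1, delta=0.0)
        assert negative_log_likelihood(ds, p) == pytest.approx(n * math.log(2))

    @pytest.mark.parametrize("alpha,beta", [(0.05, 3.0), (0.3, 1.2)])
    def test_nesting_identities(self, rng, alpha, beta):
        """single(alpha) == dual(alpha, alpha) == persev(alpha, delta=0)
        == persev_dual(alpha, alpha, delta=0) on the same record."""
        ds = random_dataset(rng)
        ref = negative_log_likelihood(ds, single(alpha, beta))
        equivalents = [
            RLParams("dual", beta=beta, alpha_pos=alpha, alpha_neg=alpha),
            RLParams("persev", beta=beta, alpha=alpha, delta=0.0),
            RLParams("persev_dual", beta=beta, alpha_pos=alpha,
                     alpha_neg=alpha, delta=0.0),
        ]
        for p in equivalents:
            assert negative_log_likelihood(ds, p) == pytest.approx(ref, abs=1e-10)

    def test_matches_stepwise_replay(self, rng):
        """The compiled likelihood equals an explicit replay through
        choice_probability / update_values."""
        ds = random_dataset(rng, n_sessions=4, session_length=50)
        params = PD
        state = ValueState()
        nll = 0.0
        prev_session = None
        for t in ds.trials:
            if t.session_index != prev_session:
                state = ValueState(state.v_front, state.v_back, 0, 0)
            prev_session = t.session_index
            if t.is_omission:
                state = ValueState(state.v_front, state.v_back, 0, 0)
                continue
            p_f = choice_probability(state, params)
            nll -= math.log(p_f if t.choice == FRONT else 1.0 - p_f)
            state = update_values(state, t.choice, int(t.rewarded), params)
        assert negative_log_likelihood(ds, params) == pytest.approx(nll, rel=1e-9)

    def test_front_back_relabel_symmetry(self, rng):
        ds = random_dataset(rng, n_sessions=4, session_length=50)
        swap = {FRONT: BACK, BACK: FRONT, OMIT: OMIT}
        mirrored = SubjectDataset("x", [
            TrialRecord(t.subject_id, t.phase_label, t.session_index,
                        t.trial_index, swap[t.choice], swap[t.high_lever],
                        t.rewarded)
            for t in ds.trials
        ])
        assert negative_log_likelihood(ds, PD) == pytest.approx(
            negative_log_likelihood(mirrored, PD), rel=1e-12)

    def test_all_omissions_error(self):
        ds = make_dataset([[OMIT] * 10])
        with pytest.raises(NoDataError):
            negative_log_likelihood(ds, single(0.1, 1.0))

    def test_finite_for_extreme_parameters(self, rng):
        ds = random_dataset(rng, n_sessions=2)
        p = RLParams("persev_dual", beta=50.0, alpha_pos=1.0, alpha_neg=1.0,
                     delta=-10.0)
        assert math.isfinite(negative_log_likelihood(ds, p))


class TestSimulateAgent:
    def test_greedy_limit_locks_on_rewarding_lever(self):
        sched = [PhaseSpec("det", p_high=1.0, p_low=0.0, high_lever=FRONT,
                           criterion=None, max_sessions=3)]
        p = RLParams("single", beta=50.0, alpha=0.5)
        ds = simulate_agent(p, sched, session_length=100,
                            rng=np.random.default_rng(0))
        tail = [t.choice for t in ds.trials[-100:]]
        assert all(c == FRONT for c in tail)

    def test_zero_omission_rate_means_no_omissions(self):
        ds = simulate_agent(PD, fixed_block_schedule(3), omission_rate=0.0,
                            rng=np.random.default_rng(1))
        assert all(t.choice != OMIT for t in ds.trials)

    def test_omission_rate_realised(self):
        ds = simulate_agent(PD, fixed_block_schedule(10), omission_rate=0.1,
                            rng=np.random.default_rng(2))
        frac = np.mean([t.is_omission for t in ds.trials])
        assert 0.07 < frac < 0.13

    def test_population_parameters_eventually_reach_criterion(self):
        """Agents at the published population estimates acquire a >80%
        high-lever preference on the 80:20 phase within tens of sessions."""
        phase = PhaseSpec("80:20 learning", p_high=0.8, p_low=0.2,
                          high_lever=FRONT, max_sessions=80)
        ds = simulate_agent(PD, [phase], session_length=100,
                            omission_rate=0.02, rng=np.random.default_rng(11))
        days = days_to_criterion(ds, phase)
        assert days is not None and days <= 80

    def test_criterion_gating_advances_phases(self):
        sched = [
            PhaseSpec("easy", p_high=1.0, p_low=0.0, high_lever=FRONT,
                      max_sessions=30),
            PhaseSpec("next", p_high=1.0, p_low=0.0, high_lever=BACK,
                      max_sessions=30),
        ]
        p = RLParams("single", beta=20.0, alpha=0.3)
        ds = simulate_agent(p, sched, session_length=100,
                            rng=np.random.default_rng(3))
        assert set(ds.phase_order) == {"easy", "next"}
        assert len({t.session_index for t in ds.trials if t.phase_label == "easy"}) < 30
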