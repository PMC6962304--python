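"""Wilcoxon signed-rank, trace smoothing, value replay, and the pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mouseprl.cohort import fixed_block_schedule, study_schedule
from mouseprl.models import RLParams, simulate_agent
from mouseprl.reporting import (
    chosen_value_bias, high_choice_indicator, moving_average_trace,
    run_pipeline, value_trace, wilcoxon_signed_rank,
)
from mouseprl.task import read_trials


def brute_force_signed_rank_p(diffs):
    """Two-sided exact p by enumerating all sign assignments (n <= 12)."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum(ranks[list(signs)]) for signs in
          (np.array(mask, dtype=bool) for mask in
           itertools.product((0, 1), repeat=len(d)))]
    ws = np.asarray(ws)
    n = len(ws)
    lower = np.sum(ws <= w_obs + 1e-9) / n
    upper = np.sum(ws >= w_obs - 1e-9) / n
    return min(1.0, 2 * min(lower, upper))


class TestWilcoxon:
    def test_one_signed_n6(self):
        r = wilcoxon_signed_rank([(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7)])
        assert r.p_value == pytest.approx(2 / 64)
        assert r.direction == "b"
        assert r.method == "exact"

    def test_all_tied_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])

    def test_swap_symmetry(self):
        pairs = [(1.0, 3.0), (4.0, 2.5), (0.5, 0.9), (2.2, 2.0), (5.0, 1.0)]
        fwd = wilcoxon_signed_rank(pairs)
        rev = wilcoxon_signed_rank([(b, a) for a, b in pairs])
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert {fwd.direction, rev.direction} == {"a", "b"}

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        for _ in range(5):
            a = rng.normal(size=12)
            b = a + rng.normal(0.4, 1.0, size=12)
            mine = wilcoxon_signed_rank(list(zip(a, b)))
            ref = stats.wilcoxon(a, b, method="exact").pvalue
            assert mine.p_value == pytest.approx(float(ref), abs=1e-12)

    def test_matches_sign_enumeration_oracle_with_ties(self, rng):
        """Integer-valued pairs force midranked ties; the DP must agree with
        brute-force enumeration of all 2^n sign assignments."""
        for _ in range(5):
            a = rng.integers(0, 5, size=10).astype(float)
            b = rng.integers(0, 5, size=10).astype(float)
            d = a - b
            if np.all(d == 0):
                continue
            mine = wilcoxon_signed_rank(list(zip(a, b)))
            assert mine.p_value == pytest.approx(brute_force_signed_rank_p(d))


class TestMovingAverage:
    def test_constant_sequence(self):
        assert (moving_average_trace([1.0] * 40) == 1.0).all()

    def test_window_one_is_identity(self):
        x = [0.0, 1.0, 1.0, 0.0]
        assert moving_average_trace(x, window=1).tolist() == x

    def test_empty_input(self):
        assert moving_average_trace([], window=25).size == 0

    def test_alternating_interior_band(self):
        out = moving_average_trace([0, 1] * 50, window=25)
        interior = out[12:-12]
        assert set(np.round(interior, 4)) == {0.48, 0.52}

    def test_strict_edges_give_nan(self):
        out = moving_average_trace([1.0] * 30, window=25, shrink_edges=False)
        assert np.isnan(out[:5]).all() and not np.isnan(out[15])

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=80),
           st.integers(1, 30))
    def test_bounded_by_input_range(self, xs, window):
        out = moving_average_trace(xs, window=window)
        assert np.nanmin(out) >= min(xs) - 1e-9
        assert np.nanmax(out) <= max(xs) + 1e-9


class TestValueTrace:
    SCHED = fixed_block_schedule(30, block=30, p_high=0.8, p_low=0.2)

    def _trace(self, params, seed):
        ds = simulate_agent(params, self.SCHED, session_length=100,
                            rng=np.random.default_rng(seed))
        return value_trace(ds, params, self.SCHED)

    def test_single_rate_tracks_true_probability(self):
        """On a long stationary 80:20 block, single-rate values hover around
        the true reward probability of the chosen lever."""
        p = RLParams("single", beta=3.0, alpha=0.1)
        assert abs(chosen_value_bias(self._trace(p, 0))) < 0.1

    def test_high_negative_rate_underestimates(self):
        p = RLParams("dual", beta=3.0, alpha_pos=0.01, alpha_neg=0.2)
        assert chosen_value_bias(self._trace(p, 1)) < 0

    def test_high_positive_rate_overestimates(self):
        p = RLParams("dual", beta=3.0, alpha_pos=0.2, alpha_neg=0.01)
        assert chosen_value_bias(self._trace(p, 2)) > 0

    def test_emits_true_probabilities_across_reversals(self):
        p = RLParams("single", beta=3.0, alpha=0.1)
        sched = fixed_block_schedule(20, block=10, p_high=0.8, p_low=0.2)
        ds = simulate_agent(p, sched, session_length=50,
                            rng=np.random.default_rng(3))
        tr = value_trace(ds, p, sched)
        assert set(np.round(tr.p_front_true.unique(), 3)) == {0.8, 0.2}


class TestHighChoiceIndicator:
    def test_omissions_dropped(self):
        from conftest import make_session
        from mouseprl.task import FRONT, BACK, OMIT
        trials = make_session([FRONT, OMIT, BACK, FRONT])
        assert high_choice_indicator(trials).tolist() == [1, 0, 1]


@pytest.fixture(scope="module")
def tiny_config():
    return {
        "synth": {
            "n_subjects": 3,
            "session_length": 80,
            "schedule": study_schedule(max_sessions=8),
            "omission_rate": 0.02,
        },
        "models": ["single", "persev_dual"],
        "n_starts": 4,
        "seed": 11,
    }


class TestPipeline:
    def test_end_to_end_outputs(self, tiny_config, tmp_path):
        out = run_pipeline(tiny_config, tmp_path / "run")
        for name in ("trials.csv", "truth.csv", "fits.csv", "comparison.csv",
                     "recovery.csv", "run.log"):
            assert (out / name).exists(), name
        fits = pd.read_csv(out / "fits.csv")
        assert set(fits.variant) == {"single", "persev_dual"}

    def test_rerun_is_byte_identical(self, tiny_config, tmp_path):
        a = run_pipeline(tiny_config, tmp_path / "a")
        b = run_pipeline(tiny_config, tmp_path / "b")
        assert (a / "fits.csv").read_bytes() == (b / "fits.csv").read_bytes()
        assert (a / "comparison.csv").read_bytes() == (b / "comparison.csv").read_bytes()

    def test_recovery_needs_full_model_in_fit_list(self, tiny_config, tmp_path):
        cfg = dict(tiny_config, models=["single", "persev"], seed=12)
        out = run_pipeline(cfg, tmp_path / "nofull")
        assert not (out / "recovery.csv").exists()
        assert "recovery skipped" in (out / "run.log").read_text()

    def test_malformed_trial_table_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject_id,phase,session,trial,choice,high_lever,rewarded,latency_ms\n"
            "s1,p,0,0,front,front,1,120\n"
            "s1,p,0,1,sideways,front,0,\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_trials(path)
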