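"""n-back schedules, D-prime scoring, exclusion rules, residualization."""

import numpy as np
import pandas as pd
import pytest

from wmnet import behavior
from wmnet.behavior import (
    ResponseLog,
    TaskSchedule,
    apply_exclusions,
    build_schedule,
    perfect_responses,
    residualize,
    score_dprime,
)
from wmnet.errors import (
    DegenerateInputError,
    ScheduleConstraintError,
    UndefinedScoreError,
)


class TestSchedule:
    def test_default_counts(self, default_schedule):
        t = default_schedule.trials
        two = t[t.condition == "2-back"]
        assert len(t) == 168 and t.block.nunique() == 12
        assert len(two) == 84
        assert two.is_target.sum() == 18
        assert two.is_lure.sum() == 15
        assert round(100 * two.is_lure.mean(), 1) == 17.9

    def test_per_block_composition(self, default_schedule):
        for _, g in default_schedule.trials.groupby("block"):
            assert g.is_target.sum() == 3
            assert (~g.is_target).sum() == 11

    def test_zero_back_targets_are_x(self, default_schedule):
        zero = default_schedule.trials.query("condition == '0-back'")
        assert (zero.is_target == (zero.letter == "x")).all()

    def test_two_back_structure_is_consistent(self, default_schedule):
        # is_target/is_lure flags must agree with the letter sequence itself.
        for _, g in default_schedule.trials.query("condition == '2-back'").groupby("block"):
            seq = list(g.letter)
            for i in range(len(seq)):
                expect_target = i >= 2 and seq[i] == seq[i - 2]
                assert bool(g.is_target.iloc[i]) == expect_target
                expect_lure = not expect_target and (
                    (i >= 1 and seq[i] == seq[i - 1]) or (i >= 3 and seq[i] == seq[i - 3])
                )
                assert bool(g.is_lure.iloc[i]) == expect_lure

    def test_infeasible_lure_count(self):
        with pytest.raises(ScheduleConstraintError):
            build_schedule(lure_count=84, seed=0)

    def test_deterministic_under_seed(self):
        a = build_schedule(seed=5).trials
        b = build_schedule(seed=5).trials
        pd.testing.assert_frame_equal(a, b)


def _mini_schedule(n_targets, n_nontargets):
    rows = [(0, "2-back", "a", True, False)] * n_targets + [
        (0, "2-back", "b", False, False)
    ] * n_nontargets
    return TaskSchedule(
        trials=pd.DataFrame(rows, columns=["block", "condition", "letter", "is_target", "is_lure"])
    )


def _log(responses):
    return ResponseLog(pd.DataFrame({"response": responses, "rt_ms": 500.0}))


class TestDPrime:
    def test_perfect_ceiling(self, default_schedule):
        log = perfect_responses(default_schedule)
        assert round(score_dprime(log, default_schedule, "2-back"), 2) == 4.34
        assert round(score_dprime(log, default_schedule, "0-back"), 2) == 4.34

    def test_interior_case_frozen_value(self):
        # 16/18 hits, 6/66 false alarms; quantiles 1.2206 and -1.3352 give 2.556.
        sched = _mini_schedule(18, 66)
        resp = ["target"] * 16 + ["nontarget"] * 2 + ["target"] * 6 + ["nontarget"] * 60
        assert score_dprime(_log(resp), sched, "2-back") == pytest.approx(2.556, abs=5e-3)

    def test_equal_rates_give_zero(self):
        sched = _mini_schedule(10, 20)
        resp = ["target"] * 5 + ["nontarget"] * 5 + ["target"] * 10 + ["nontarget"] * 10
        assert score_dprime(_log(resp), sched, "2-back") == pytest.approx(0.0, abs=1e-12)

    def test_trial_order_invariance(self):
        sched = _mini_schedule(10, 20)
        resp = np.array(["target"] * 7 + ["nontarget"] * 3 + ["target"] * 4 + ["nontarget"] * 16)
        d0 = score_dprime(_log(resp), sched, "2-back")
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(resp))
        sched_p = TaskSchedule(trials=sched.trials.iloc[perm].reset_index(drop=True))
        d1 = score_dprime(_log(resp[perm]), sched_p, "2-back")
        assert d0 == pytest.approx(d1, abs=1e-12)

    def test_missing_dropped_from_both_sides(self):
        # 2 of 18 targets missing: hit rate should use N = 16.
        sched = _mini_schedule(18, 66)
        resp = ["missing"] * 2 + ["target"] * 16 + ["target"] * 6 + ["nontarget"] * 60
        full = ["target"] * 16 + ["nontarget"] * 0 + ["target"] * 6 + ["nontarget"] * 60
        d_miss = score_dprime(_log(resp), sched, "2-back")
        sched16 = _mini_schedule(16, 66)
        d_ref = score_dprime(_log(full), sched16, "2-back")
        assert d_miss == pytest.approx(d_ref, abs=1e-12)

    def test_all_targets_missing_is_undefined(self):
        sched = _mini_schedule(3, 5)
        resp = ["missing"] * 3 + ["nontarget"] * 5
        with pytest.raises(UndefinedScoreError):
            score_dprime(_log(resp), sched, "2-back")

    def test_unknown_condition(self, default_schedule):
        with pytest.raises(ValueError):
            score_dprime(perfect_responses(default_schedule), default_schedule, "3-back")


def _behavior_table(n, **overrides):
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "d_prime_2back": rng.normal(2.5, 0.8, n),
            "d_prime_0back": rng.normal(3.6, 0.5, n),
            "rt_difference": rng.normal(126, 100, n),
            "episodic_memory": rng.normal(31, 8, n),
            "item_familiarity": rng.normal(3.5, 10, n),
        }
    )
    for k, v in overrides.items():
        df.loc[v[0], k] = v[1]
    return df


class TestExclusions:
    def test_high_overall_missing_flagged(self, default_schedule):
        rng = np.random.default_rng(1)
        miss_idx = rng.choice(168, 70, replace=False)
        resp = np.array(["nontarget"] * 168, dtype=object)
        resp[default_schedule.trials.is_target.to_numpy()] = "target"
        resp[miss_idx] = "missing"
        logs = [_log(resp), perfect_responses(default_schedule)]
        table = _behavior_table(2)
        out = apply_exclusions(table, logs, default_schedule)
        assert out.excluded[0] and "a" in out.exclusion_reasons[0]
        assert not out.excluded[1]

    def test_block_target_missing_rule(self, default_schedule):
        # One missing target per block trips the >30% per-block criterion
        # (1 of 3 targets); three such blocks trigger reason (b).
        resp = np.where(default_schedule.trials.is_target, "target", "nontarget").astype(object)
        for b in (0, 1, 2):
            idx = default_schedule.trials.query("block == @b and is_target").index[0]
            resp[idx] = "missing"
        out = apply_exclusions(_behavior_table(1), [_log(resp)], default_schedule)
        assert "b" in out.exclusion_reasons[0]

    def test_clean_table_unchanged(self, default_schedule):
        logs = [perfect_responses(default_schedule)] * 3
        out = apply_exclusions(_behavior_table(3), logs, default_schedule)
        assert not out.excluded.any()
        assert (out.exclusion_reasons == "").all()

    def test_four_sd_outlier_flagged(self):
        table = _behavior_table(200)
        mu, sd = table.episodic_memory.mean(), table.episodic_memory.std(ddof=1)
        table.loc[0, "episodic_memory"] = mu + 5 * sd
        out = apply_exclusions(table)
        assert "d" in out.exclusion_reasons[0]
        assert out.excluded.sum() == 1

    def test_incomplete_data_flagged(self):
        table = _behavior_table(5)
        table.loc[2, "d_prime_2back"] = np.nan
        out = apply_exclusions(table)
        assert "e" in out.exclusion_reasons[2]

    def test_flags_monotone_in_missingness(self, default_schedule):
        rng = np.random.default_rng(4)
        resp = np.where(default_schedule.trials.is_target, "target", "nontarget").astype(object)
        resp[rng.choice(168, 55, replace=False)] = "missing"
        more = resp.copy()
        more[rng.choice(168, 110, replace=False)] = "missing"
        r1 = apply_exclusions(_behavior_table(1), [_log(resp)], default_schedule).exclusion_reasons[0]
        r2 = apply_exclusions(_behavior_table(1), [_log(more)], default_schedule).exclusion_reasons[0]
        assert set(r1.split(",")) - {""} <= set(r2.split(",")) - {""}


class TestResidualize:
    def test_single_level_equals_zscore(self):
        rng = np.random.default_rng(0)
        v = rng.normal(3, 2, 50)
        out = residualize(v, None)
        assert np.allclose(out, (v - v.mean()) / v.std(ddof=1))

    def test_exact_offsets_degenerate(self):
        factors = pd.DataFrame({"batch": [0, 0, 1, 1, 2, 2]})
        v = np.array([2.0, 2.0, 0.0, 0.0, -2.0, -2.0])
        with pytest.warns(UserWarning, match="degenerate"):
            out = residualize(v, factors)
        assert np.allclose(out, 0.0)

    def test_batch_means_removed(self):
        rng = np.random.default_rng(2)
        batch = rng.integers(0, 3, 120)
        v = np.array([2.0, 0.0, -2.0])[batch] + rng.normal(0, 1, 120)
        out = residualize(v, pd.DataFrame({"batch": batch}))
        for b in range(3):
            assert abs(out[batch == b].mean()) < 1e-10

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateInputError):
            residualize(np.ones(10), None)

    def test_matrix_form_removes_batch_structure(self):
        rng = np.random.default_rng(5)
        batch = pd.DataFrame({"b": rng.integers(0, 2, 60)})
        X = rng.normal(0, 1, (60, 40)) + 3.0 * batch.b.to_numpy()[:, None]
        R = behavior.residualize_matrix(X, batch)
        assert np.allclose(R.std(axis=0, ddof=1), 1.0)
        for lvl in (0, 1):
            assert np.abs(R[batch.b.to_numpy() == lvl].mean(axis=0)).max() < 1e-10
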