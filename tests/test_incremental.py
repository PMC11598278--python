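"""Loss blending, schedules, head expansion, replay increments."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emgreplay import densenet
from emgreplay.densenet import DenseNetSpec, TrainConfig, build_model
from emgreplay.incremental import (
    IncrementSchedule,
    LossBlend,
    SCHEDULE_TABLE,
    blended_loss,
    class_increment_run,
    compute_lambda,
    cross_entropy,
    expand_head,
    generic_schedule,
    increment_step,
    schedule_for,
    train_initial,
)
from emgreplay.replay import rebuild_buffer
from tests.conftest import make_toy_dataset

# Independent transcription of the published 12-day increment strategy
# (test day -> [2 initial days, then 9 increments]).
TABLE3_ROWS = {
    1: [12, 11, 10, 9, 8, 7, 6, 5, 4, 3, 2],
    2: [12, 11, 10, 9, 8, 7, 6, 5, 4, 3, 1],
    3: [12, 11, 10, 9, 8, 7, 6, 5, 1, 4, 2],
    4: [12, 11, 10, 9, 8, 7, 1, 6, 2, 5, 3],
    5: [12, 11, 10, 9, 1, 8, 2, 7, 3, 6, 4],
    6: [12, 11, 1, 10, 2, 9, 3, 8, 4, 7, 5],
    7: [12, 1, 2, 11, 3, 10, 4, 9, 5, 8, 6],
    8: [1, 2, 3, 4, 12, 5, 11, 6, 10, 7, 9],
    9: [1, 2, 3, 4, 5, 6, 12, 7, 11, 8, 10],
    10: [1, 2, 3, 4, 5, 6, 7, 8, 12, 9, 11],
    11: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12],
    12: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11],
}


class TestCrossEntropy:
    def test_perfect_one_hot_predictions(self):
        probs = np.eye(4)
        assert cross_entropy(probs, np.arange(4)) == 0.0

    def test_uniform_predictions_give_log_c(self):
        for C in (2, 5, 7):
            probs = np.full((3, C), 1.0 / C)
            assert abs(cross_entropy(probs, np.zeros(3, dtype=int)) - math.log(C)) < 1e-12

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0.05, 1.0, size=(5, 3))
        probs = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 3, size=5)
        onehot = np.zeros((5, 3))
        onehot[np.arange(5), labels] = 1.0
        ref = 0.0
        for i in range(5):
            for c in range(3):
                ref -= onehot[i, c] * math.log(probs[i, c])
        ref /= 5
        assert abs(cross_entropy(probs, labels) - ref) < 1e-12
        assert abs(cross_entropy(probs, onehot) - ref) < 1e-12

    def test_zero_probability_clamped_not_infinite(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss = cross_entropy(probs, np.array([1, 1]))
        assert np.isfinite(loss)


class TestComputeLambda:
    def test_floored_at_printed_minimum(self):
        blend = LossBlend(mode="time", n_incl=140, n_total=1400, floor=0.2)
        assert compute_lambda(blend) == 0.2  # raw ratio 0.1 floored

    def test_all_incremental_gives_one(self):
        assert compute_lambda(LossBlend(mode="time", n_incl=50, n_total=50)) == 1.0

    def test_class_mode_is_class_ratio(self):
        blend = LossBlend(mode="class", n_new_classes=1, n_total_classes=7)
        assert compute_lambda(blend) == pytest.approx(1 / 7)

    def test_incl_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            compute_lambda(LossBlend(mode="time", n_incl=10, n_total=5))

    @settings(derandomize=True, max_examples=50)
    @given(n_total=st.integers(10, 5000), a=st.integers(1, 5000), b=st.integers(1, 5000))
    def test_monotone_in_incremental_count(self, n_total, a, b):
        a, b = sorted((min(a, n_total), min(b, n_total)))
        la = compute_lambda(LossBlend(mode="time", n_incl=a, n_total=n_total))
        lb = compute_lambda(LossBlend(mode="time", n_incl=b, n_total=n_total))
        assert la <= lb
        assert la >= 0.2  # never below the floor


class TestBlendedLoss:
    def test_edge_weights_select_single_terms(self):
        assert blended_loss(3.0, 5.0, 1.0) == 5.0
        assert blended_loss(3.0, 5.0, 0.0) == 3.0

    def test_printed_arithmetic_case(self):
        assert blended_loss(1.0, 2.0, 0.2) == pytest.approx(1.2)

    @settings(derandomize=True, max_examples=100)
    @given(
        loss_r=st.floats(0, 50, allow_nan=False),
        loss_i=st.floats(0, 50, allow_nan=False),
        lam=st.floats(0, 1, allow_nan=False),
    )
    def test_convexity_bounds(self, loss_r, loss_i, lam):
        total = blended_loss(loss_r, loss_i, lam)
        lo, hi = min(loss_r, loss_i), max(loss_r, loss_i)
        assert lo - 1e-9 <= total <= hi + 1e-9

    def test_weight_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            blended_loss(1.0, 1.0, 1.5)


class TestSchedules:
    def test_every_row_partitions_the_twelve_days(self):
        for day in range(1, 13):
            s = schedule_for(day)
            assert s.all_days == set(range(1, 13))
            assert len(s.initial_days) == 2
            assert len(s.increment_days) == 9

    @pytest.mark.parametrize("day", list(range(1, 13)))
    def test_rows_match_published_protocol(self, day):
        s = schedule_for(day)
        assert [*s.initial_days, *s.increment_days] == TABLE3_ROWS[day]

    def test_rows_are_span_sorted(self):
        """Initial days carry the two largest spans; increments then arrive in
        non-increasing span order (the published row for test day 7 lists its
        two initial days as (12, 1) — spans 5, 6 — so the initial pair itself
        is order-free)."""
        for day in range(1, 13):
            s = schedule_for(day)
            spans = [abs(d - day) for d in (*s.initial_days, *s.increment_days)]
            assert sorted(spans[:2], reverse=True) == sorted(spans, reverse=True)[:2]
            inc = spans[1:]  # after the (unordered) initial pair
            assert all(a >= b for a, b in zip(inc, inc[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            schedule_for(13)

    @pytest.mark.parametrize("day", [1, 5])
    def test_generic_later_first_matches_table_rows(self, day):
        s = generic_schedule(day, 12, tie_break="later-first")
        assert [*s.initial_days, *s.increment_days] == TABLE3_ROWS[day]

    def test_generic_small_study_partitions(self):
        s = generic_schedule(2, 4)
        assert s.all_days == {1, 2, 3, 4}
        assert len(s.initial_days) == 2
        assert len(s.increment_days) == 1

    def test_tie_break_policies_differ(self):
        later = generic_schedule(6, 11, tie_break="later-first")
        earlier = generic_schedule(6, 11, tie_break="earlier-first")
        assert later != earlier
        assert later.all_days == earlier.all_days

    def test_duplicate_days_rejected(self):
        with pytest.raises(ValueError):
            IncrementSchedule(1, (2, 2), (3,))


class TestExpandHead:
    def test_old_logits_bit_identical(self, toy_spec):
        model = build_model(toy_spec, seed=0)
        x = np.random.default_rng(0).normal(size=(6, 4, 100)).astype(np.float32)
        before = model.forward(x, train=False)
        bigger = expand_head(model, 1)
        after = bigger.forward(x, train=False)
        assert np.array_equal(before, after[:, :2])

    def test_new_class_logits_start_at_zero(self, toy_spec):
        model = build_model(toy_spec, seed=0)
        bigger = expand_head(model, 2)
        x = np.random.default_rng(1).normal(size=(3, 4, 100)).astype(np.float32)
        assert np.all(bigger.forward(x, train=False)[:, 2:] == 0.0)

    def test_expand_twice_equals_expand_once_by_two(self, toy_spec):
        model = build_model(toy_spec, seed=0)
        x = np.random.default_rng(2).normal(size=(3, 4, 100)).astype(np.float32)
        twice = expand_head(expand_head(model, 1), 1)
        once = expand_head(model, 2)
        assert np.array_equal(twice.forward(x, False), once.forward(x, False))

    def test_source_model_untouched(self, toy_spec):
        model = build_model(toy_spec, seed=0)
        expand_head(model, 1)
        assert model.n_classes == 2


class TestIncrementStep:
    def test_lambda_one_equals_plain_training(self, toy_spec):
        old = make_toy_dataset(n_per_class=8, seed=0)
        incl = make_toy_dataset(n_per_class=8, seed=1)
        cfg = TrainConfig(epochs=2, batch_size=8, seed=5)
        buffer = rebuild_buffer([old], "uniform", total_budget=8)

        via_step = build_model(toy_spec, seed=3)
        via_step, _ = increment_step(
            via_step, buffer, incl,
            LossBlend(mode="time", n_incl=8, n_total=8, floor=0.2), cfg,
        )
        plain = build_model(toy_spec, seed=3)
        plain, _ = densenet.train(plain, incl, cfg)
        for a, b in zip(via_step.state_arrays(), plain.state_arrays()):
            assert np.array_equal(a, b)

    def test_buffer_provenance_gains_new_day(self, toy_spec):
        old = make_toy_dataset(n_per_class=8, seed=0)
        old.day_index[:] = 1
        incl = make_toy_dataset(n_per_class=8, seed=1)
        incl.day_index[:] = 2
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0)
        buffer = rebuild_buffer([old], "uniform", total_budget=8)
        model = build_model(toy_spec, seed=0)
        model, buffer2 = increment_step(
            model, buffer, incl,
            LossBlend(mode="time", n_incl=16, n_total=32, floor=0.2), cfg,
            seen_old_datasets=[old],
        )
        assert set(buffer2.days) == {1, 2}
        assert len(buffer2) <= buffer2.total_budget

    def test_empty_incremental_set_is_noop(self, toy_spec):
        from emgreplay.io import SegmentDataset

        old = make_toy_dataset(n_per_class=4, seed=0)
        buffer = rebuild_buffer([old], "uniform", total_budget=4)
        model = build_model(toy_spec, seed=0)
        before = [a.copy() for a in model.state_arrays()]
        model, buffer2 = increment_step(
            model, buffer, SegmentDataset.empty(("G0", "G1"), length=100),
            LossBlend(mode="time", n_incl=1, n_total=2, floor=0.2),
            TrainConfig(epochs=1, seed=0),
        )
        assert all(np.array_equal(a, b) for a, b in zip(before, model.state_arrays()))
        assert buffer2 is buffer

    def test_empty_buffer_with_partial_lambda_rejected(self, toy_spec):
        incl = make_toy_dataset(n_per_class=4, seed=0)
        model = build_model(toy_spec, seed=0)
        with pytest.raises(ValueError, match="buffer"):
            increment_step(
                model, None, incl,
                LossBlend(mode="time", n_incl=1, n_total=10, floor=0.2),
                TrainConfig(epochs=1, seed=0),
            )


class TestTrainInitial:
    def test_pools_datasets_and_trains(self, toy_spec, fast_cfg):
        a = make_toy_dataset(n_per_class=12, seed=0)
        b = make_toy_dataset(n_per_class=12, seed=1)
        model, history = train_initial([a, b], toy_spec, fast_cfg)
        assert len(history["train_loss"]) <= fast_cfg.epochs
        ids, _ = densenet.predict(model, a)
        assert float((ids == a.labels).mean()) > 0.9

    def test_empty_initial_rejected(self, toy_spec, fast_cfg):
        with pytest.raises(ValueError):
            train_initial([], toy_spec, fast_cfg)
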