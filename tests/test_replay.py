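"""Exemplar selection strategies and replay-buffer maintenance."""

import numpy as np
import pytest
from sklearn.cluster import DBSCAN

from emgreplay.io import SegmentDataset
from emgreplay.replay import (
    DbscanParams,
    STRATEGIES,
    rebuild_buffer,
    rms_features,
    select_dbscan,
    select_intermediate,
    select_random,
    select_uniform,
)


def dataset_from_rms(rms_targets: np.ndarray, labels, class_names=("A",),
                     day: int = 1, length: int = 50) -> SegmentDataset:
    """Segments whose per-channel RMS equals the requested values exactly
    (constant-valued channels)."""
    n = len(rms_targets)
    segs = np.repeat(np.asarray(rms_targets, dtype=np.float32)[:, :, None], length, axis=2)
    labels = np.asarray(labels, dtype=np.int64)
    reps = np.zeros(n, dtype=np.int64)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        reps[idx] = np.arange(idx.size)
    return SegmentDataset(segs, labels, class_names,
                          np.full(n, day, dtype=np.int64), reps)


class TestRmsFeatures:
    def test_constant_segment_rms_is_absolute_value(self):
        ds = dataset_from_rms(np.array([[0.5, -1.5, 2.0, 0.0]]), [0])
        np.testing.assert_allclose(rms_features(ds)[0], [0.5, 1.5, 2.0, 0.0])

    def test_zero_segment(self):
        ds = dataset_from_rms(np.zeros((1, 4)), [0])
        assert np.all(rms_features(ds) == 0.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        segs = rng.normal(size=(50, 4, 200))
        got = rms_features(segs)
        for s in range(50):
            for i in range(4):
                acc = 0.0
                for k in range(200):
                    acc += segs[s, i, k] ** 2
                assert abs(got[s, i] - np.sqrt(acc / 200)) < 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rms_features(np.zeros((0, 4, 100)))


class TestDbscanSelection:
    def _clustered_with_outliers(self, seed=0):
        rng = np.random.default_rng(seed)
        tight = rng.normal([1.0, 1.0, 0.5, 0.2], 0.02, size=(30, 4))
        outliers = np.array([[5.0, 5.0, 5.0, 5.0],
                             [0.0, 4.0, 0.0, 4.0],
                             [8.0, 0.1, 0.1, 0.1]])
        rms = np.vstack([tight, outliers])
        return dataset_from_rms(np.abs(rms), [0] * 33), np.arange(30, 33)

    def test_planted_outliers_never_selected(self):
        ds, outlier_idx = self._clustered_with_outliers()
        chosen = select_dbscan(ds, budget_per_class=10)
        assert len(chosen) == 10
        assert not set(chosen) & set(outlier_idx)
        # independent check: a reference density clustering on the same
        # features labels exactly those points as noise
        feats = rms_features(ds)
        z = (feats - feats.mean(0)) / feats.std(0)
        ref = DBSCAN(eps=1.0, min_samples=5).fit(z)
        assert set(np.flatnonzero(ref.labels_ == -1)) == set(outlier_idx)

    def test_noise_only_backfills_after_non_noise(self):
        ds, outlier_idx = self._clustered_with_outliers()
        chosen = select_dbscan(ds, budget_per_class=32)
        # 30 non-noise points exist, so at most 2 of 3 outliers may appear
        assert len(chosen) == 32
        assert sum(i in outlier_idx for i in chosen) == 2

    def test_duplicated_point_is_core_and_ranked_first(self):
        rng = np.random.default_rng(1)
        dup = np.tile([2.0, 1.0, 0.5, 0.25], (20, 1))
        spread = np.abs(rng.normal([2.0, 1.0, 0.5, 0.25], 1.5, size=(10, 4)))
        ds = dataset_from_rms(np.vstack([dup, spread]), [0] * 30)
        chosen = select_dbscan(ds, budget_per_class=1,
                               params=DbscanParams(min_samples=5))
        assert chosen[0] in range(20)

    def test_budget_saturation_returns_all(self):
        ds, _ = self._clustered_with_outliers()
        assert set(select_dbscan(ds, budget_per_class=50)) == set(range(33))

    def test_all_noise_falls_back_to_centroid_ranking(self, caplog):
        rng = np.random.default_rng(2)
        scattered = np.abs(rng.uniform(0, 10, size=(12, 4)))
        ds = dataset_from_rms(scattered, [0] * 12)
        chosen = select_dbscan(ds, budget_per_class=4,
                               params=DbscanParams(eps=1e-6, min_samples=5))
        assert len(chosen) == 4


class TestRandomSelection:
    def test_seeded_determinism_and_saturation(self):
        ds = dataset_from_rms(np.abs(np.random.default_rng(0).normal(size=(20, 4))), [0] * 20)
        a = select_random(ds, 5, seed=3)
        b = select_random(ds, 5, seed=3)
        assert np.array_equal(a, b)
        assert set(select_random(ds, 20, seed=0)) == set(range(20))

    def test_selection_frequency_matches_hypergeometric(self):
        n, budget, n_seeds = 20, 5, 200
        ds = dataset_from_rms(np.abs(np.random.default_rng(1).normal(size=(n, 4))), [0] * n)
        counts = np.zeros(n)
        for seed in range(n_seeds):
            counts[select_random(ds, budget, seed=seed)] += 1
        p = budget / n
        sigma = np.sqrt(n_seeds * p * (1 - p))
        assert np.all(np.abs(counts - n_seeds * p) <= 3 * sigma)


class TestUniformSelection:
    def test_spacing_100_reps_budget_10(self):
        ds = dataset_from_rms(np.ones((100, 4)), [0] * 100)
        chosen = select_uniform(ds, 10)
        # round(j * 99 / 9) for j = 0..9
        assert chosen.tolist() == [0, 11, 22, 33, 44, 55, 66, 77, 88, 99]

    def test_budget_one_takes_first(self):
        ds = dataset_from_rms(np.ones((9, 4)), [0] * 9)
        assert select_uniform(ds, 1).tolist() == [0]

    def test_budget_equals_n_is_identity(self):
        ds = dataset_from_rms(np.ones((7, 4)), [0] * 7)
        assert select_uniform(ds, 7).tolist() == list(range(7))

    def test_follows_rep_order_not_storage_order(self):
        ds = dataset_from_rms(np.ones((4, 4)), [0] * 4)
        ds.rep_index = np.array([3, 2, 1, 0])
        assert select_uniform(ds, 2).tolist() == [0, 3]  # first and last rep


class TestIntermediateSelection:
    def test_central_block_100_reps_budget_10(self):
        ds = dataset_from_rms(np.ones((100, 4)), [0] * 100)
        assert select_intermediate(ds, 10).tolist() == list(range(45, 55))

    def test_three_reps_budget_one_takes_middle(self):
        ds = dataset_from_rms(np.ones((3, 4)), [0] * 3)
        assert select_intermediate(ds, 1).tolist() == [1]

    def test_budget_equals_n_returns_all(self):
        ds = dataset_from_rms(np.ones((6, 4)), [0] * 6)
        assert select_intermediate(ds, 6).tolist() == list(range(6))


class TestSelectorInvariants:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    @pytest.mark.parametrize("budget", [1, 4, 50])
    def test_unique_in_range_exact_count_per_class(self, strategy, budget):
        rng = np.random.default_rng(10)
        n_per = (12, 30)
        rms = np.abs(rng.normal(1.0, 0.5, size=(sum(n_per), 4)))
        labels = [0] * n_per[0] + [1] * n_per[1]
        ds = dataset_from_rms(rms, labels, class_names=("A", "B"))
        select = {
            "dbscan": lambda: select_dbscan(ds, budget, seed=0),
            "random": lambda: select_random(ds, budget, seed=0),
            "uniform": lambda: select_uniform(ds, budget),
            "intermediate": lambda: select_intermediate(ds, budget),
        }[strategy]
        chosen = select()
        assert len(set(chosen)) == len(chosen)
        assert np.all((chosen >= 0) & (chosen < len(ds)))
        for c, n_c in enumerate(n_per):
            got = sum(ds.labels[i] == c for i in chosen)
            assert got == min(budget, n_c)


class TestRebuildBuffer:
    def _two_day_study(self, n_per_class=20, n_classes=7):
        rng = np.random.default_rng(3)
        days = []
        for day in (1, 2):
            n = n_per_class * n_classes
            rms = np.abs(rng.normal(1.0, 0.3, size=(n, 4)))
            labels = np.repeat(np.arange(n_classes), n_per_class)
            names = tuple(f"C{i}" for i in range(n_classes))
            days.append(dataset_from_rms(rms, labels, class_names=names, day=day))
        return days

    def test_equal_quota_two_days_seven_classes(self):
        days = self._two_day_study()
        buf = rebuild_buffer(days, "uniform", total_budget=140)
        assert len(buf) == 140
        for day in (1, 2):
            day_mask = buf.dataset.day_index == day
            for c in range(7):
                assert int((day_mask & (buf.dataset.labels == c)).sum()) == 10

    def test_budget_covering_everything_keeps_whole_dataset(self):
        days = self._two_day_study(n_per_class=3)[:1]
        buf = rebuild_buffer(days, "random", total_budget=100)
        assert len(buf) == 21

    def test_deterministic_for_fixed_seed(self):
        days = self._two_day_study()
        a = rebuild_buffer(days, "random", 50, seed=4)
        b = rebuild_buffer(days, "random", 50, seed=4)
        assert np.array_equal(a.dataset.segments, b.dataset.segments)

    def test_unknown_strategy_lists_the_four(self):
        days = self._two_day_study()
        with pytest.raises(ValueError, match="dbscan, random, uniform, intermediate"):
            rebuild_buffer(days, "herding", 10)

    def test_remainder_goes_to_earliest_days(self):
        days = self._two_day_study(n_per_class=5, n_classes=2)
        buf = rebuild_buffer(days, "uniform", total_budget=7)
        # 7 over 4 cells -> base 1, remainder 3 to day-1 cells first
        d1 = int((buf.dataset.day_index == 1).sum())
        d2 = int((buf.dataset.day_index == 2).sum())
        assert (d1, d2) == (4, 3)

    def test_buffer_never_exceeds_budget(self):
        days = self._two_day_study()
        for b in (1, 13, 140, 1000):
            assert len(rebuild_buffer(days, "uniform", b)) <= b
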