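"""Evaluation designs: single-day CV, cross-day matrix, incremental curves.

Four designs probe the cross-session stability of the classifier:

* stratified k-fold cross-validation within a single day (the ceiling:
  train and test share a session, so no drift);
* a cross-day train/test matrix (rows = training day, columns = test day,
  diagonal masked) exposing the accuracy drop under electrode displacement
  and signal drift;
* a least-squares trend of mean accuracy against time span |train - test|;
* the incremental-learning curve: accuracy on a held-out test day after
  the initial model and after each replay increment.

Accuracies are fractions in [0, 1] internally; convert to percentages only
at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from emgreplay import densenet
from emgreplay.densenet import DenseNet1d, DenseNetSpec, TrainConfig
from emgreplay.incremental import (
    IncrementSchedule,
    LossBlend,
    increment_step,
    train_initial,
)
from emgreplay.io import SegmentDataset
from emgreplay.replay import DbscanParams, rebuild_buffer


def accuracy(preds, truth) -> float:
    """Fraction of exactly matching class ids."""
    preds = np.asarray(preds)
    truth = np.asarray(truth)
    if preds.shape != truth.shape:
        raise ValueError(f"length mismatch: {preds.shape} vs {truth.shape}")
    if preds.size == 0:
        raise ValueError("need at least one prediction")
    return float((preds == truth).mean())


def confusion(preds, truth, n_classes: int) -> np.ndarray:
    """Count matrix with rows = truth, columns = predicted."""
    preds = np.asarray(preds, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if preds.shape != truth.shape:
        raise ValueError("length mismatch")
    if preds.size and (max(preds.max(), truth.max()) >= n_classes or
                       min(preds.min(), truth.min()) < 0):
        raise ValueError(f"class ids outside 0..{n_classes - 1}")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (truth, preds), 1)
    return m


@dataclass
class CrossDayMatrix:
    """Train-day x test-day accuracy matrix with a masked diagonal."""

    accuracy: np.ndarray  # (n_days, n_days), NaN on the diagonal
    days: tuple[int, ...]

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=np.float64)
        off = ~np.eye(len(self.days), dtype=bool)
        vals = self.accuracy[off]
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def off_diagonal_mean(self) -> float:
        off = ~np.eye(len(self.days), dtype=bool)
        return float(self.accuracy[off].mean())


@dataclass
class TrendFit:
    """Least-squares line of mean accuracy over time span."""

    slope: float
    intercept: float
    spans: np.ndarray
    mean_accuracies: np.ndarray


def kfold_single_day(day_set: SegmentDataset, k: int, spec: DenseNetSpec,
                     cfg: TrainConfig) -> list[float]:
    """Stratified k-fold CV within one day; returns k test accuracies."""
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(day_set.labels, minlength=day_set.n_classes)
    present = counts[counts > 0]
    if present.size and present.min() < k:
        raise ValueError(
            f"smallest class has {present.min()} segments; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    accs = []
    for fold, (tr, te) in enumerate(skf.split(day_set.segments, day_set.labels)):
        model = densenet.build_model(spec, seed=cfg.seed + fold)
        model, _ = densenet.train(model, day_set.subset(tr), cfg)
        ids, _ = densenet.predict(model, day_set.subset(te))
        accs.append(accuracy(ids, day_set.labels[te]))
    return accs


def cross_day_analysis(study: list[SegmentDataset], spec: DenseNetSpec,
                       cfg: TrainConfig) -> CrossDayMatrix:
    """Train one model per day; fill the off-diagonal test accuracies."""
    if len(study) < 2:
        raise ValueError("need at least 2 days")
    days = tuple(int(ds.day_index[0]) for ds in study)
    n = len(study)
    mat = np.full((n, n), np.nan)
    for i, train_ds in enumerate(study):
        model = densenet.build_model(spec, seed=cfg.seed + i)
        model, _ = densenet.train(model, train_ds, cfg)
        for j, test_ds in enumerate(study):
            if i == j:
                continue
            ids, _ = densenet.predict(model, test_ds)
            mat[i, j] = accuracy(ids, test_ds.labels)
    return CrossDayMatrix(accuracy=mat, days=days)


def span_trend(matrix: CrossDayMatrix) -> TrendFit:
    """Fit mean accuracy against time span |train_day - test_day|."""
    days = np.asarray(matrix.days)
    span = np.abs(days[:, None] - days[None, :])
    off = ~np.eye(len(days), dtype=bool)
    spans = np.unique(span[off])
    if spans.size < 2:
        raise ValueError("need at least 2 distinct spans for a trend")
    means = np.array([matrix.accuracy[off & (span == s)].mean() for s in spans])
    slope, intercept = np.polyfit(spans.astype(float), means, 1)
    return TrendFit(slope=float(slope), intercept=float(intercept),
                    spans=spans, mean_accuracies=means)


def incremental_curve(study: list[SegmentDataset], schedule: IncrementSchedule,
                      strategy: str, spec: DenseNetSpec, cfg: TrainConfig,
                      lambda_floor: float = 0.2, replay_budget: int | None = None,
                      params: DbscanParams | None = None,
                      no_replay: bool = False) -> list[float]:
    """Test-day accuracy after the initial model and after each increment.

    Entry 0 is the initial model; entries 1..n follow the schedule's
    increment days, so the curve has ``n_increments + 1`` entries. The
    time-mode lambda uses ``N_Incl / N_Total`` with ``N_Total`` the total
    sample count seen so far (floored at ``lambda_floor``). With
    ``no_replay=True`` every increment uses lambda = 1 (the
    catastrophic-forgetting ablation).
    """
    by_day = {int(ds.day_index[0]): ds for ds in study}
    missing = schedule.all_days - set(by_day)
    if missing:
        raise ValueError(f"schedule references days absent from the study: {sorted(missing)}")
    test_ds = by_day[schedule.test_day]
    initial_sets = [by_day[d] for d in schedule.initial_days]
    model, _ = train_initial(initial_sets, spec, cfg)

    def test_acc(m: DenseNet1d) -> float:
        ids, _ = densenet.predict(m, test_ds)
        return accuracy(ids, test_ds.labels)

    curve = [test_acc(model)]
    budget = replay_budget if replay_budget is not None else sum(len(s) for s in initial_sets)
    buffer = rebuild_buffer(initial_sets, strategy, budget, params, cfg.seed)
    seen = list(initial_sets)
    for day in schedule.increment_days:
        incl = by_day[day]
        n_total = sum(len(s) for s in seen) + len(incl)
        blend = (
            LossBlend(mode="time", n_incl=len(incl), n_total=n_total, floor=1.0)
            if no_replay
            else LossBlend(mode="time", n_incl=len(incl), n_total=n_total,
                           floor=lambda_floor)
        )
        model, buffer = increment_step(
            model, buffer, incl, blend, cfg, seen_old_datasets=seen, params=params
        )
        seen.append(incl)
        curve.append(test_acc(model))
    return curve
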