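"""Replay-based incremental training.

An initial model is trained on the two sessions with the largest time span
from the test session; the remaining sessions arrive one at a time as
increments. At each increment the optimizer descends on a convex blend of
two cross-entropy terms — one on a minibatch from the replay buffer of old
data (loss_R) and one on a minibatch of the incremental data (loss_I):

    loss_T = (1 - lambda) * loss_R + lambda * loss_I ,
    lambda = max(N_Incl / N_Total, floor)        (time-incremental mode)
    lambda = n_new_classes / n_total_classes     (class-incremental mode)

In time mode the floor defaults to 0.2 — newer sessions carry higher
validity, so the incremental term is never down-weighted below it. In class
mode the incremental set contains only the new class, and lambda is the
class ratio (1/7 for one new gesture among seven). lambda is static within
one increment; after each increment the replay buffer is rebuilt over all
seen old datasets.

Class increments expand the classifier head: old class rows are copied
bit-exactly and new rows start at zero, so old-class logits are unchanged
until training resumes.

The blend is applied at minibatch granularity with paired replay and
incremental batches (rather than pre-mixing the datasets), which keeps
loss_R and loss_I separately measurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from emgreplay import densenet, nn
from emgreplay.densenet import DenseNet1d, DenseNetSpec, TrainConfig
from emgreplay.io import SegmentDataset
from emgreplay.replay import DbscanParams, ReplayBuffer, rebuild_buffer

logger = logging.getLogger(__name__)

#: Verbatim 12-day increment schedule: test day -> (2 initial days, 9 increment
#: days), ordered by decreasing time span from the test day. The tie-breaking
#: direction differs between test days 1-7 and 8-12 in the source protocol, so
#: the table is embedded literally rather than re-derived.
SCHEDULE_TABLE: dict[int, tuple[tuple[int, int], tuple[int, ...]]] = {
    1: ((12, 11), (10, 9, 8, 7, 6, 5, 4, 3, 2)),
    2: ((12, 11), (10, 9, 8, 7, 6, 5, 4, 3, 1)),
    3: ((12, 11), (10, 9, 8, 7, 6, 5, 1, 4, 2)),
    4: ((12, 11), (10, 9, 8, 7, 1, 6, 2, 5, 3)),
    5: ((12, 11), (10, 9, 1, 8, 2, 7, 3, 6, 4)),
    6: ((12, 11), (1, 10, 2, 9, 3, 8, 4, 7, 5)),
    7: ((12, 1), (2, 11, 3, 10, 4, 9, 5, 8, 6)),
    8: ((1, 2), (3, 4, 12, 5, 11, 6, 10, 7, 9)),
    9: ((1, 2), (3, 4, 5, 6, 12, 7, 11, 8, 10)),
    10: ((1, 2), (3, 4, 5, 6, 7, 8, 12, 9, 11)),
    11: ((1, 2), (3, 4, 5, 6, 7, 8, 9, 10, 12)),
    12: ((1, 2), (3, 4, 5, 6, 7, 8, 9, 10, 11)),
}


@dataclass
class IncrementSchedule:
    """Partition of study days into test / initial-training / increments."""

    test_day: int
    initial_days: tuple[int, ...]
    increment_days: tuple[int, ...]

    def __post_init__(self) -> None:
        self.initial_days = tuple(self.initial_days)
        self.increment_days = tuple(self.increment_days)
        days = [self.test_day, *self.initial_days, *self.increment_days]
        if len(set(days)) != len(days):
            raise ValueError("schedule days must be distinct")

    @property
    def all_days(self) -> set[int]:
        return {self.test_day, *self.initial_days, *self.increment_days}


def schedule_for(test_day: int) -> IncrementSchedule:
    """The verbatim 12-day schedule row for ``test_day``."""
    if test_day not in SCHEDULE_TABLE:
        raise ValueError(f"test_day must be in 1..12, got {test_day}")
    initial, increments = SCHEDULE_TABLE[test_day]
    return IncrementSchedule(test_day, initial, increments)


def generic_schedule(test_day: int, n_days: int,
                     tie_break: str = "later-first") -> IncrementSchedule:
    """Span-sorted schedule for an arbitrary study length.

    Non-test days are sorted by decreasing distance ``|day - test_day|``;
    the two farthest become the initial training days, the rest become
    increments (closer sessions, with higher validity, arrive later...
    i.e. earlier in the increment order the farther they are). Equal-span
    ties are broken by the chosen policy.
    """
    if n_days < 3:
        raise ValueError("need n_days >= 3")
    if not 1 <= test_day <= n_days:
        raise ValueError(f"test_day must be in 1..{n_days}")
    if tie_break not in ("later-first", "earlier-first"):
        raise ValueError("tie_break must be 'later-first' or 'earlier-first'")
    sign = -1 if tie_break == "later-first" else 1
    days = sorted(
        (d for d in range(1, n_days + 1) if d != test_day),
        key=lambda d: (-abs(d - test_day), sign * d),
    )
    return IncrementSchedule(test_day, tuple(days[:2]), tuple(days[2:]))


# ---------------------------------------------------------------------------
# loss algebra
# ---------------------------------------------------------------------------

def cross_entropy(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy of probability rows against labels.

    ``labels`` may be integer class ids or a one-hot matrix. Zero
    probabilities at a true class are clamped by ``eps`` (logged) so no
    infinity propagates.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[0] < 1:
        raise ValueError("probs must be a non-empty (n, C) matrix")
    labels = np.asarray(labels)
    if labels.ndim == 2:  # one-hot
        onehot = labels.astype(np.float64)
    else:
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(labels)), labels.astype(np.int64)] = 1.0
    p_true = (probs * onehot).sum(axis=1)
    if np.any(p_true <= 0):
        logger.warning("zero probability at a true class; clamping by eps")
    return float(-np.log(np.maximum(p_true, eps)).mean())


@dataclass
class LossBlend:
    """Inputs for the incremental-dataset weight lambda.

    Time mode uses sample counts with a floor; class mode uses the class
    ratio.
    """

    mode: str = "time"
    n_incl: int = 0
    n_total: int = 0
    floor: float = 0.2
    n_new_classes: int = 1
    n_total_classes: int = 7

    def __post_init__(self) -> None:
        if self.mode not in ("time", "class"):
            raise ValueError("mode must be 'time' or 'class'")
        if not 0.0 <= self.floor <= 1.0:
            raise ValueError("floor must lie in [0, 1]")


def compute_lambda(blend: LossBlend) -> float:
    """The incremental-dataset weight for the two-term loss."""
    if blend.mode == "time":
        if blend.n_incl <= 0 or blend.n_total <= 0:
            raise ValueError("sample counts must be positive")
        if blend.n_incl > blend.n_total:
            raise ValueError("n_incl cannot exceed n_total")
        return max(blend.n_incl / blend.n_total, blend.floor)
    if blend.n_new_classes <= 0 or blend.n_total_classes <= 0:
        raise ValueError("class counts must be positive")
    if blend.n_new_classes > blend.n_total_classes:
        raise ValueError("n_new_classes cannot exceed n_total_classes")
    return blend.n_new_classes / blend.n_total_classes


def blended_loss(loss_r: float, loss_i: float, lam: float) -> float:
    """Convex combination (1 - lambda) * loss_R + lambda * loss_I."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if loss_r < 0 or loss_i < 0:
        raise ValueError("losses must be non-negative")
    return (1.0 - lam) * loss_r + lam * loss_i


# ---------------------------------------------------------------------------
# training steps
# ---------------------------------------------------------------------------

def train_initial(initial_sets: list[SegmentDataset], spec: DenseNetSpec,
                  cfg: TrainConfig) -> tuple[DenseNet1d, dict]:
    """Train the initial model on the pooled initial-day datasets."""
    if not initial_sets or sum(len(s) for s in initial_sets) == 0:
        raise ValueError("initial datasets are empty")
    pooled = SegmentDataset.concat(initial_sets)
    model = densenet.build_model(spec, seed=cfg.seed)
    return densenet.train(model, pooled, cfg)


def _replay_stream(n: int, batch_size: int, rng):
    """Yield endless replay minibatch index arrays, reshuffling each pass."""
    while True:
        perm = rng.permutation(n)
        for s in range(0, n, batch_size):
            yield perm[s : s + batch_size]


def increment_step(model: DenseNet1d, buffer: ReplayBuffer | None,
                   incl: SegmentDataset, blend: LossBlend, cfg: TrainConfig,
                   seen_old_datasets: list[SegmentDataset] | None = None,
                   params: DbscanParams | None = None) -> tuple[DenseNet1d, ReplayBuffer]:
    """One replay increment: blended-loss training, then buffer rebuild.

    Each optimization step draws one minibatch from the replay buffer and
    one from the incremental set, computes loss_R and loss_I, and descends
    on their lambda-blend. With ``lambda == 1`` the buffer is ignored and
    the step reduces to plain training on ``incl`` (bit-identical to
    :func:`emgreplay.densenet.train` at the same seed).

    Afterwards the buffer is rebuilt over all seen old datasets including
    ``incl``; pass ``seen_old_datasets`` (one per previously seen day) to
    rebuild from full datasets — otherwise the buffer's stored exemplars
    stand in for the old days.
    """
    if len(incl) == 0:
        logger.warning("empty incremental set; increment is a no-op")
        return model, buffer
    lam = compute_lambda(blend)
    if lam < 1.0 and (buffer is None or len(buffer) == 0):
        raise ValueError("lambda < 1 requires a non-empty replay buffer")

    if lam >= 1.0:
        model, _ = densenet.train(model, incl, cfg)
    else:
        rng = np.random.default_rng(cfg.seed)
        xI = np.ascontiguousarray(incl.segments, dtype=np.float32)
        yI = incl.labels
        xR = np.ascontiguousarray(buffer.dataset.segments, dtype=np.float32)
        yR = buffer.dataset.labels
        opt = nn.Adam(model.parameters(), lr=cfg.lr)
        replay_batches = _replay_stream(len(xR), cfg.batch_size, rng)
        for _epoch in range(cfg.epochs):
            perm = rng.permutation(len(xI))
            for s in range(0, len(perm), cfg.batch_size):
                ib = perm[s : s + cfg.batch_size]
                rb = next(replay_batches)
                logits_r = model.forward(xR[rb], train=True)
                _, d_r = nn.softmax_cross_entropy(logits_r, yR[rb])
                model.backward(d_r)
                grads_r = [p.grad for p in model.parameters()]
                logits_i = model.forward(xI[ib], train=True)
                _, d_i = nn.softmax_cross_entropy(logits_i, yI[ib])
                model.backward(d_i)
                for p, gr in zip(model.parameters(), grads_r):
                    p.grad = (1.0 - lam) * gr + lam * p.grad
                opt.step()

    old = list(seen_old_datasets) if seen_old_datasets is not None else _buffer_days(buffer)
    strategy = buffer.strategy if buffer is not None else "uniform"
    budget = buffer.total_budget if buffer is not None else len(incl)
    new_buffer = rebuild_buffer(old + [incl], strategy, budget, params, cfg.seed)
    return model, new_buffer


def _buffer_days(buffer: ReplayBuffer | None) -> list[SegmentDataset]:
    if buffer is None:
        return []
    ds = buffer.dataset
    return [ds.subset(np.flatnonzero(ds.day_index == d)) for d in np.unique(ds.day_index)]


def expand_head(model: DenseNet1d, n_new_classes: int) -> DenseNet1d:
    """Grow the classifier head by ``n_new_classes`` outputs.

    Pre-existing class weights and bias are copied bit-exactly and new rows
    are zero-initialized, so old-class logits on any input are unchanged
    and new-class logits are exactly 0 before training. Expanding twice by
    one equals expanding once by two.
    """
    if n_new_classes < 1:
        raise ValueError("n_new_classes must be >= 1")
    out = model.copy()
    old = model.head
    n_old, n_in = old.w.data.shape
    head = nn.Linear(n_in, n_old + n_new_classes)
    head.w.data = np.zeros((n_old + n_new_classes, n_in), dtype=np.float32)
    head.w.data[:n_old] = old.w.data
    head.b.data = np.zeros(n_old + n_new_classes, dtype=np.float32)
    head.b.data[:n_old] = old.b.data
    out.head = head
    return out


def class_increment_run(datasets_by_day: dict[int, SegmentDataset],
                        held_out_class: int, schedule: IncrementSchedule,
                        spec: DenseNetSpec, cfg: TrainConfig,
                        strategy: str = "dbscan", replay_budget: int | None = None,
                        params: DbscanParams | None = None):
    """Class-incremental protocol: learn a new gesture on top of the rest.

    The initial model is trained on the other ``C - 1`` classes from the
    initial days; the head is then expanded by one output and the held-out
    class's data are fed day by day (initial days first, then increment
    days) with ``lambda = 1 / C`` while old-class exemplars are replayed.

    Old classes are re-labeled 0..C-2 (original order preserved) and the
    new class takes id C-1. Returns ``(model, metrics)`` where ``metrics``
    has one dict per increment with overall and new-class accuracy on the
    test day.
    """
    from emgreplay.evaluation import accuracy  # local import: avoid cycle

    any_ds = next(iter(datasets_by_day.values()))
    n_classes = any_ds.n_classes
    if not 0 <= held_out_class < n_classes:
        raise ValueError(f"held_out_class must be in 0..{n_classes - 1}")
    old_ids = [c for c in range(n_classes) if c != held_out_class]
    remap = {c: i for i, c in enumerate(old_ids)}
    remap[held_out_class] = n_classes - 1
    new_names = tuple(any_ds.class_names[c] for c in old_ids) + (
        any_ds.class_names[held_out_class],
    )

    def remap_subset(ds: SegmentDataset, keep_new: bool, keep_old: bool) -> SegmentDataset:
        mask = np.zeros(len(ds), dtype=bool)
        if keep_old:
            mask |= ds.labels != held_out_class
        if keep_new:
            mask |= ds.labels == held_out_class
        sub = ds.subset(np.flatnonzero(mask))
        labels = np.array([remap[int(l)] for l in sub.labels], dtype=np.int64)
        return SegmentDataset(sub.segments, labels, new_names, sub.day_index, sub.rep_index)

    old_spec = DenseNetSpec(**{**spec.__dict__, "n_classes": n_classes - 1,
                               "block_sizes": spec.block_sizes})
    initial_sets = [remap_subset(datasets_by_day[d], keep_new=False, keep_old=True)
                    for d in schedule.initial_days]
    model, _ = train_initial(initial_sets, old_spec, cfg)
    model = expand_head(model, 1)

    blend = LossBlend(mode="class", n_new_classes=1, n_total_classes=n_classes)
    budget = replay_budget if replay_budget is not None else sum(len(s) for s in initial_sets)
    buffer = rebuild_buffer(initial_sets, strategy, budget, params, cfg.seed)
    seen_old = list(initial_sets)

    test_ds = remap_subset(datasets_by_day[schedule.test_day], keep_new=True, keep_old=True)
    new_mask = test_ds.labels == n_classes - 1
    metrics: list[dict] = []
    increment_days = [*schedule.initial_days, *schedule.increment_days]
    for day in increment_days:
        if day not in datasets_by_day:
            continue
        incl = remap_subset(datasets_by_day[day], keep_new=True, keep_old=False)
        model, buffer = increment_step(
            model, buffer, incl, blend, cfg, seen_old_datasets=seen_old, params=params
        )
        seen_old.append(incl)
        ids, _ = densenet.predict(model, test_ds)
        metrics.append({
            "day": day,
            "overall_acc": accuracy(ids, test_ds.labels),
            "new_class_acc": accuracy(ids[new_mask], test_ds.labels[new_mask])
            if new_mask.any() else float("nan"),
        })
    return model, metrics
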