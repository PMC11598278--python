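"""Replay-buffer exemplar selection.

The replay buffer stores a budgeted subset of old-task segments. Four
selection strategies are provided, applied independently per gesture class:

* ``dbscan`` — featurize each segment by its per-channel RMS amplitude
  (a 4-vector), z-score the features, cluster with DBSCAN, drop
  noise-labeled points, and rank the rest by ascending Euclidean distance
  to the centroid of the largest cluster's core points (the densest, most
  representative region). Core points themselves sit at distance 0 from
  *some* core point, so the centroid reference is what makes the ranking
  total.
* ``random`` — uniform without replacement, seeded.
* ``uniform`` — evenly spaced positions over the repetition order
  (captures slow within-session variation such as fatigue).
* ``intermediate`` — the contiguous central block of the repetition order
  (transitional executions at the start/end of a session are assumed less
  representative).

:func:`rebuild_buffer` reapplies a strategy over every (day, class) cell
each time a new increment arrives, splitting the total budget equally
across the cells actually present (remainder to the earliest days).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from emgreplay.io import SegmentDataset

logger = logging.getLogger(__name__)

STRATEGIES = ("dbscan", "random", "uniform", "intermediate")


@dataclass
class DbscanParams:
    """DBSCAN knobs in (optionally z-scored) RMS feature space.

    ``eps="auto"`` sets the radius to the 90th percentile of 4-nearest-
    neighbor distances of the class's feature cloud.
    """

    eps: float | str = "auto"
    min_samples: int = 5
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.eps != "auto" and not (isinstance(self.eps, (int, float)) and self.eps > 0):
            raise ValueError("eps must be positive or 'auto'")
        if self.min_samples < 2:
            raise ValueError("min_samples must be >= 2")


@dataclass
class ReplayBuffer:
    """Budgeted store of old-task segments with provenance."""

    dataset: SegmentDataset
    strategy: str
    total_budget: int

    def __post_init__(self) -> None:
        if len(self.dataset) > self.total_budget:
            raise ValueError("buffer exceeds its budget")

    def __len__(self) -> int:
        return len(self.dataset)

    @property
    def days(self) -> np.ndarray:
        return np.unique(self.dataset.day_index)


def rms_features(segs: SegmentDataset | np.ndarray) -> np.ndarray:
    """Per-channel RMS amplitude, shape (n_segments, n_channels).

    Entry (s, i) = sqrt(mean over samples of channel i squared) — the
    standard sEMG intensity descriptor.
    """
    x = segs.segments if isinstance(segs, SegmentDataset) else np.asarray(segs)
    if x.shape[0] == 0:
        raise ValueError("need at least one segment")
    return np.sqrt(np.mean(x.astype(np.float64) ** 2, axis=2))


# ---------------------------------------------------------------------------
# per-class pickers (indices are positions within one class's index array)
# ---------------------------------------------------------------------------

def _auto_eps(feats: np.ndarray) -> float:
    """90th percentile of 4-nearest-neighbor distances (self excluded)."""
    k = min(4, len(feats) - 1)
    if k < 1:
        return 1.0
    nn = NearestNeighbors(n_neighbors=k + 1).fit(feats)
    dist, _ = nn.kneighbors(feats)
    eps = float(np.percentile(dist[:, k], 90))
    return eps if eps > 0 else 1.0


def _zscore(feats: np.ndarray) -> np.ndarray:
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    return (feats - feats.mean(axis=0)) / sd


def _dbscan_rank(feats: np.ndarray, params: DbscanParams) -> np.ndarray:
    """Rank row indices by representativeness (best first)."""
    if params.standardize:
        feats = _zscore(feats)
    eps = _auto_eps(feats) if params.eps == "auto" else float(params.eps)
    min_samples = min(params.min_samples, len(feats))
    db = DBSCAN(eps=eps, min_samples=min_samples).fit(feats)
    labels = db.labels_
    non_noise = labels >= 0
    if not non_noise.any():
        logger.warning("all points noise-labeled; falling back to overall centroid")
        d = np.linalg.norm(feats - feats.mean(axis=0), axis=1)
        return np.argsort(d, kind="stable")
    # centroid of the largest cluster's core points
    clusters, counts = np.unique(labels[non_noise], return_counts=True)
    biggest = clusters[counts.argmax()]
    core = np.zeros(len(feats), dtype=bool)
    core[db.core_sample_indices_] = True
    anchor = feats[core & (labels == biggest)].mean(axis=0)
    d = np.linalg.norm(feats - anchor, axis=1)
    order = np.argsort(d, kind="stable")
    # non-noise points first (same distance ranking), then noise backfill
    return np.concatenate([order[non_noise[order]], order[~non_noise[order]]])


def _pick_dbscan(segs: SegmentDataset, idx: np.ndarray, budget: int,
                 params: DbscanParams, rng=None) -> np.ndarray:
    if idx.size <= budget:
        return idx
    rank = _dbscan_rank(rms_features(segs.subset(idx)), params)
    return idx[rank[:budget]]


def _pick_random(segs: SegmentDataset, idx: np.ndarray, budget: int,
                 params=None, rng=None) -> np.ndarray:
    take = min(budget, idx.size)
    return np.sort(rng.choice(idx, size=take, replace=False))


def _uniform_positions(n: int, budget: int) -> np.ndarray:
    """Rounded linear spacing over 0..n-1 including both ends; budget 1 -> first."""
    if budget >= n:
        return np.arange(n)
    if budget == 1:
        return np.array([0])
    pos = np.round(np.arange(budget) * (n - 1) / (budget - 1)).astype(np.int64)
    return np.unique(pos)  # ties collapse to the lower index


def _pick_uniform(segs: SegmentDataset, idx: np.ndarray, budget: int,
                  params=None, rng=None) -> np.ndarray:
    order = idx[np.argsort(segs.rep_index[idx], kind="stable")]
    return np.sort(order[_uniform_positions(order.size, budget)])


def _pick_intermediate(segs: SegmentDataset, idx: np.ndarray, budget: int,
                       params=None, rng=None) -> np.ndarray:
    order = idx[np.argsort(segs.rep_index[idx], kind="stable")]
    take = min(budget, order.size)
    start = (order.size - take) // 2
    return np.sort(order[start : start + take])


_PICKERS = {
    "dbscan": _pick_dbscan,
    "random": _pick_random,
    "uniform": _pick_uniform,
    "intermediate": _pick_intermediate,
}


def _class_indices(segs: SegmentDataset):
    for c in range(segs.n_classes):
        idx = np.flatnonzero(segs.labels == c)
        if idx.size == 0:
            warnings.warn(f"class {c} has no segments; skipped", stacklevel=3)
            continue
        yield c, idx


def _select(strategy: str, segs: SegmentDataset, budget_per_class: int,
            params: DbscanParams | None, seed: int) -> np.ndarray:
    if budget_per_class < 1:
        raise ValueError("budget_per_class must be >= 1")
    params = params or DbscanParams()
    rng = np.random.default_rng(seed)
    pick = _PICKERS[strategy]
    out = [pick(segs, idx, budget_per_class, params, rng)
           for _c, idx in _class_indices(segs)]
    return np.concatenate(out) if out else np.zeros(0, dtype=np.int64)


def select_dbscan(segs: SegmentDataset, budget_per_class: int,
                  params: DbscanParams | None = None, seed: int = 0) -> np.ndarray:
    """Per class: keep the ``budget_per_class`` most representative segments.

    Representativeness is distance to the densest cluster's core centroid;
    noise points are used only to backfill when non-noise points run out.
    ``seed`` is accepted for interface symmetry (the method is
    deterministic).
    """
    return _select("dbscan", segs, budget_per_class, params, seed)


def select_random(segs: SegmentDataset, budget_per_class: int, seed: int = 0) -> np.ndarray:
    """Uniform selection without replacement, per class, seeded."""
    return _select("random", segs, budget_per_class, None, seed)


def select_uniform(segs: SegmentDataset, budget_per_class: int) -> np.ndarray:
    """Evenly spaced positions of the rep_index-sorted list, per class."""
    return _select("uniform", segs, budget_per_class, None, 0)


def select_intermediate(segs: SegmentDataset, budget_per_class: int) -> np.ndarray:
    """The contiguous central block of the rep_index order, per class."""
    return _select("intermediate", segs, budget_per_class, None, 0)


def _cell_quotas(cells: list[tuple[int, int]], total_budget: int) -> dict[tuple[int, int], int]:
    """Equal split over present (day, class) cells; remainder to earliest days."""
    n_cells = len(cells)
    base = total_budget // n_cells
    quotas = {cell: base for cell in cells}
    for cell in cells[: total_budget - base * n_cells]:  # day-major order
        quotas[cell] += 1
    if base == 0:
        warnings.warn(
            "total_budget below one segment per (day, class) cell; "
            "later cells receive nothing", stacklevel=3,
        )
    return quotas


def rebuild_buffer(old_datasets: list[SegmentDataset], strategy: str,
                   total_budget: int, params: DbscanParams | None = None,
                   seed: int = 0) -> ReplayBuffer:
    """Reconstruct the replay buffer over all seen old datasets.

    ``old_datasets`` holds one dataset per stored day (any order; day
    identity comes from each dataset's ``day_index``). The budget is split
    equally over the (day, class) cells present in the data, the strategy
    applied cell by cell, and the resulting buffer never exceeds
    ``total_budget``.
    """
    if strategy not in STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; choose one of {', '.join(STRATEGIES)}"
        )
    if not old_datasets:
        raise ValueError("need at least one old dataset")
    if total_budget < 1:
        raise ValueError("total_budget must be >= 1")
    params = params or DbscanParams()
    cells = [
        (d, int(c))
        for d, ds in enumerate(old_datasets)
        for c in np.unique(ds.labels)
    ]
    if not cells:
        return ReplayBuffer(
            SegmentDataset.empty(old_datasets[0].class_names), strategy, total_budget
        )
    quotas = _cell_quotas(cells, total_budget)
    pick = _PICKERS[strategy]
    parts = []
    for d, ds in enumerate(old_datasets):
        rng = np.random.default_rng(np.random.SeedSequence([seed, d]))
        chosen = []
        for c in np.unique(ds.labels):
            q = quotas[(d, int(c))]
            if q == 0:
                continue
            idx = np.flatnonzero(ds.labels == c)
            chosen.append(pick(ds, idx, q, params, rng))
        if chosen:
            parts.append(ds.subset(np.concatenate(chosen)))
    merged = (
        SegmentDataset.concat(parts)
        if parts
        else SegmentDataset.empty(old_datasets[0].class_names)
    )
    return ReplayBuffer(dataset=merged, strategy=strategy, total_budget=total_budget)
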