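"""Filtering and energy-threshold action segmentation.

The preprocessing chain is: 20-300 Hz band-pass (4th-order Butterworth,
applied forward-backward for zero phase), 50 Hz notch (2nd-order IIR,
quality factor 30), then segmentation. Segmentation divides the signal into
non-overlapping blocks of N samples, computes the block's average energy
across the four channels,

    E_w(t) = (1/4) * sum_i (1/N) * sum_n |x_i[n]|^2 ,

and declares an action onset when E_w exceeds a rest-statistics threshold
(rest mean + k * rest SD, estimated on an initial baseline window) for a
minimum run of consecutive blocks; the offset is declared symmetrically.
Detected active intervals of varying effective length are standardized to
exactly 1000 samples by centering a window on the interval midpoint —
flanking raw signal (not zero padding) fills short intervals, and windows
are clamped at the recording edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from emgreplay.io import Recording, SegmentDataset


class SegmentationError(RuntimeError):
    """Raised when rest statistics cannot be estimated from the recording."""


@dataclass
class EnergySeries:
    """Per-block average energy E_w(t) (signal units squared)."""

    values: np.ndarray
    block_size: int
    hop: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("energy values must be non-negative")

    def block_to_sample(self, t: int) -> int:
        """Start sample of block ``t``."""
        return t * self.hop


@dataclass
class SegmenterParams:
    """Energy-threshold segmenter knobs.

    The moving-window size and threshold are not dictated by the protocol;
    defaults are non-overlapping 64-sample blocks with an onset threshold of
    rest mean + 3 SD sustained for 3 blocks (192 samples — comfortably below
    the shortest plausible action but above zero-phase filter smear), rest
    statistics taken from the first ``baseline_window`` samples.
    """

    block_size: int = 64
    hop: int = 64
    onset_k: float = 3.0
    offset_k: float = 3.0
    min_active_blocks: int = 3
    baseline_window: int = 1000
    target_length: int = 1000

    def __post_init__(self) -> None:
        if self.block_size < 1 or self.hop < 1:
            raise ValueError("block_size and hop must be >= 1")
        if self.min_active_blocks < 1:
            raise ValueError("min_active_blocks must be >= 1")
        if self.target_length < 1:
            raise ValueError("target_length must be >= 1")


def bandpass(rec: Recording, low: float = 20.0, high: float = 300.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass, per channel."""
    if not 0 < low < high < rec.fs / 2:
        raise ValueError(f"band ({low}, {high}) Hz must lie within (0, fs/2)")
    sos = sps.butter(order, (low, high), btype="bandpass", fs=rec.fs, output="sos")
    return rec.replace_samples(sps.sosfiltfilt(sos, rec.samples, axis=1))


def notch(rec: Recording, freq: float = 50.0, quality: float = 30.0) -> Recording:
    """Zero-phase IIR notch (band-stop) at ``freq`` Hz."""
    if not 0 < freq < rec.fs / 2:
        raise ValueError(f"notch frequency {freq} Hz must lie within (0, fs/2)")
    b, a = sps.iirnotch(freq, quality, fs=rec.fs)
    return rec.replace_samples(sps.filtfilt(b, a, rec.samples, axis=1))


def average_energy(rec: Recording, block_size: int = 64, hop: int = 64) -> EnergySeries:
    """Blockwise average energy across channels.

    Block ``t`` covers samples ``[t*hop, t*hop + block_size)``; its value is
    the mean over channels of the mean squared sample within the block.
    """
    n = rec.n_samples
    if block_size > n:
        raise ValueError(f"block_size {block_size} exceeds recording length {n}")
    n_blocks = (n - block_size) // hop + 1
    sq = rec.samples ** 2
    # cumulative sum gives each block's within-channel mean in O(n)
    csum = np.concatenate(
        [np.zeros((rec.n_channels, 1)), np.cumsum(sq, axis=1)], axis=1
    )
    starts = np.arange(n_blocks) * hop
    block_sums = csum[:, starts + block_size] - csum[:, starts]
    values = block_sums.mean(axis=0) / block_size
    return EnergySeries(values=values, block_size=block_size, hop=hop)


def standardize_window(samples: np.ndarray, start: int, end: int,
                       target_length: int = 1000) -> np.ndarray:
    """Cut a ``target_length`` window centered on [start, end)'s midpoint.

    Flanking raw signal is included when the interval is shorter than the
    target; the window is clamped at the recording edges (so it may be
    off-center near them). Requires the recording to be at least
    ``target_length`` samples long.
    """
    n = samples.shape[1]
    if n < target_length:
        raise ValueError(
            f"recording of {n} samples is shorter than target {target_length}"
        )
    mid = (start + end) // 2
    w0 = mid - target_length // 2
    w0 = min(max(w0, 0), n - target_length)
    return samples[:, w0 : w0 + target_length].copy()


def detect_intervals(rec: Recording, params: SegmenterParams
                     ) -> tuple[list[tuple[int, int]], EnergySeries, float]:
    """Threshold the energy series into active sample intervals.

    Returns (intervals, energy_series, threshold). Intervals are half-open
    sample index pairs, sorted and non-overlapping by construction.
    """
    if rec.n_samples <= params.baseline_window + params.block_size:
        raise SegmentationError(
            "recording shorter than baseline_window + block_size; "
            "cannot estimate rest statistics"
        )
    energy = average_energy(rec, params.block_size, params.hop)
    n_base = max(1, (params.baseline_window - params.block_size) // params.hop + 1)
    rest = energy.values[:n_base]
    mu, sd = float(rest.mean()), float(rest.std())
    onset_thr = mu + params.onset_k * sd
    offset_thr = mu + params.offset_k * sd
    post = energy.values[n_base:]
    if post.size and np.all(post > onset_thr):
        raise SegmentationError(
            "no post-baseline block falls below the onset threshold — no rest "
            "found; review baseline_window / onset_k"
        )
    intervals: list[tuple[int, int]] = []
    t, n_blocks = 0, energy.values.size
    while t < n_blocks:
        if energy.values[t] > onset_thr:
            run = t
            while run < n_blocks and energy.values[run] > offset_thr:
                run += 1
            if run - t >= params.min_active_blocks:
                start = energy.block_to_sample(t)
                end = energy.block_to_sample(run - 1) + params.block_size
                intervals.append((start, min(end, rec.n_samples)))
            t = run
        else:
            t += 1
    return intervals, energy, onset_thr


def segment_actions(rec: Recording, params: SegmenterParams | None = None,
                    class_names: tuple[str, ...] = ("unlabeled",)
                    ) -> tuple[SegmentDataset, list[tuple[int, int]]]:
    """Detect actions and emit standardized unlabeled segments.

    Every emitted segment has exactly ``params.target_length`` samples
    regardless of the detected interval's effective length. Labels are set
    to 0 ("unlabeled"); ``rep_index`` records detection order.
    """
    params = params or SegmenterParams()
    intervals, _, _ = detect_intervals(rec, params)
    segs = [
        standardize_window(rec.samples, s, e, params.target_length)
        for s, e in intervals
    ]
    n = len(segs)
    ds = SegmentDataset(
        np.stack(segs) if n else np.zeros((0, rec.n_channels, params.target_length)),
        np.zeros(n, dtype=np.int64),
        class_names,
        np.full(n, rec.day_index, dtype=np.int64),
        np.arange(n, dtype=np.int64),
    )
    return ds, intervals


def label_detections(intervals: list[tuple[int, int]], truth,
                     min_overlap: float = 0.5) -> np.ndarray:
    """Label detected intervals from ground truth by fractional overlap.

    Each detection gets the class of the ground-truth interval it overlaps
    by at least ``min_overlap`` of that interval's length, else -1.
    """
    labels = np.full(len(intervals), -1, dtype=np.int64)
    for i, (ds, de) in enumerate(intervals):
        best, best_frac = -1, 0.0
        for ts, te, cls in truth:
            ov = max(0, min(de, te) - max(ds, ts)) / max(1, te - ts)
            if ov > best_frac:
                best, best_frac = cls, ov
        if best_frac >= min_overlap:
            labels[i] = best
    return labels
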