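"""File formats for session recordings, segment datasets and experiment configs.

Formats are versioned and human-inspectable where practical:

* **Session recordings** — plain CSV with a commented header block (format
  version, sampling rate, subject, day, channel names) followed by one column
  per channel.
* **Segment datasets / replay buffers** — ``.npz`` containers holding the
  segment tensor plus label/day/rep arrays and a JSON metadata blob (segments
  are the hot path, so a binary array container is used).
* **Experiment configs** — YAML (or JSON, which YAML subsumes).

All indices are 0-based internally; ``day_index`` stays 1-based to match the
acquisition-day naming (days 1..12). Intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

SESSION_FORMAT = "emgreplay-session"
SEGMENTS_FORMAT = "emgreplay-segments"
FORMAT_VERSION = (1, 0)  # (major, minor); readers reject unknown majors

DEFAULT_CHANNELS = ("ch1", "ch2", "ch3", "ch4")


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk format."""


@dataclass
class Recording:
    """A raw multi-channel sEMG session.

    Parameters
    ----------
    samples
        Signal matrix, shape ``(n_channels, n_samples)``, arbitrary mV-scale
        units. Must be finite.
    fs
        Sampling rate in Hz. Protocol-conformant data use 1000 Hz and
        4 channels; other values are allowed but trigger a warning.
    subject_id
        Free-form subject identifier.
    day_index
        1-based acquisition day.
    channel_names
        One name per channel.
    """

    samples: np.ndarray
    fs: float = 1000.0
    subject_id: str = "S1"
    day_index: int = 1
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_channels, n_samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.day_index < 1:
            raise ValueError("day_index is 1-based and must be >= 1")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel count")
        if self.n_channels != 4 or self.fs != 1000.0:
            warnings.warn(
                f"non-conformant recording: {self.n_channels} channels at "
                f"{self.fs} Hz (protocol uses 4 channels at 1000 Hz)",
                stacklevel=2,
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def replace_samples(self, samples: np.ndarray) -> "Recording":
        """Return a copy of this recording carrying new samples."""
        return dataclasses.replace(self, samples=samples)


@dataclass
class SegmentDataset:
    """Standardized action segments with labels and provenance.

    ``segments`` has shape ``(n_segments, n_channels, segment_length)`` with
    ``segment_length == 1000`` for protocol-conformant data. ``rep_index``
    records execution order within each (day, class) cell.
    """

    segments: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]
    day_index: np.ndarray
    rep_index: np.ndarray

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.day_index = np.asarray(self.day_index, dtype=np.int64)
        self.rep_index = np.asarray(self.rep_index, dtype=np.int64)
        self.class_names = tuple(self.class_names)
        if self.segments.ndim != 3:
            raise ValueError("segments must be 3-D (n, channels, length)")
        n = self.segments.shape[0]
        for name, arr in (
            ("labels", self.labels),
            ("day_index", self.day_index),
            ("rep_index", self.rep_index),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} does not match {n} segments")
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels outside the declared class set")

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def segment_length(self) -> int:
        return self.segments.shape[2]

    def subset(self, indices) -> "SegmentDataset":
        idx = np.asarray(indices, dtype=np.int64)
        return SegmentDataset(
            self.segments[idx],
            self.labels[idx],
            self.class_names,
            self.day_index[idx],
            self.rep_index[idx],
        )

    @staticmethod
    def concat(datasets: list["SegmentDataset"]) -> "SegmentDataset":
        if not datasets:
            raise ValueError("need at least one dataset")
        names = datasets[0].class_names
        for d in datasets[1:]:
            if d.class_names != names:
                raise ValueError("datasets declare different class sets")
        return SegmentDataset(
            np.concatenate([d.segments for d in datasets]),
            np.concatenate([d.labels for d in datasets]),
            names,
            np.concatenate([d.day_index for d in datasets]),
            np.concatenate([d.rep_index for d in datasets]),
        )

    @staticmethod
    def empty(class_names: tuple[str, ...], n_channels: int = 4, length: int = 1000) -> "SegmentDataset":
        z = np.zeros(0, dtype=np.int64)
        return SegmentDataset(
            np.zeros((0, n_channels, length), dtype=np.float32), z, class_names, z, z
        )


@dataclass
class ExperimentConfig:
    """Bundle of pipeline hyperparameters with validated defaults.

    Training defaults follow the study protocol: learning rate 0.001, batch
    size 128, 50 epochs, 20 % validation split.
    """

    lr: float = 0.001
    epochs: int = 50
    batch_size: int = 128
    val_fraction: float = 0.2
    seed: int = 0
    # preprocessing
    band_low: float = 20.0
    band_high: float = 300.0
    notch_freq: float = 50.0
    block_size: int = 64
    hop: int = 64
    onset_k: float = 3.0
    offset_k: float = 3.0
    min_active_blocks: int = 2
    baseline_window: int = 1000
    # replay
    replay_budget: int = 140
    replay_strategy: str = "dbscan"
    # loss blending
    lambda_mode: str = "time"
    lambda_floor: float = 0.2

    def __post_init__(self) -> None:
        for name in ("lr", "epochs", "batch_size", "band_low", "band_high",
                     "notch_freq", "block_size", "hop", "onset_k", "offset_k",
                     "min_active_blocks", "baseline_window", "replay_budget"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if not 0.0 <= self.lambda_floor <= 1.0:
            raise ValueError("lambda_floor must lie in [0, 1]")
        if self.lambda_mode not in ("time", "class"):
            raise ValueError("lambda_mode must be 'time' or 'class'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(ExperimentConfig)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return ExperimentConfig(**d)


# ---------------------------------------------------------------------------
# session CSV format
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path, overwrite: bool = False):
    """Write a session recording as CSV with a commented header block.

    Refuses to clobber an existing file unless ``overwrite`` is set.
    """
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    header = [
        f"# format: {SESSION_FORMAT} v{FORMAT_VERSION[0]}.{FORMAT_VERSION[1]}",
        f"# fs: {rec.fs!r}",
        f"# subject_id: {rec.subject_id}",
        f"# day_index: {rec.day_index}",
        "# channels: " + ",".join(rec.channel_names),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        # repr round-trips float64 exactly through the text format
        for row in rec.samples.T:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    return path


def read_recording(path) -> Recording:
    """Read a session recording written by :func:`write_recording`."""
    path = os.fspath(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        body = line[1:].strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    _check_format(meta, SESSION_FORMAT, path)
    for key in ("fs", "subject_id", "day_index", "channels"):
        if key not in meta:
            raise FormatError(f"{path}: header missing required field '{key}'")
    channels = tuple(c.strip() for c in meta["channels"].split(","))
    n_ch = len(channels)
    if n_ch != 4:
        raise FormatError(
            f"{path}: expected 4 channels in header, found {n_ch}"
        )
    for lineno, line in enumerate(lines[n_header:], start=n_header + 1):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != n_ch:
            raise FormatError(
                f"{path}:{lineno}: expected {n_ch} channel columns, found {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from exc
    samples = (
        np.array(rows, dtype=np.float64).T
        if rows
        else np.zeros((n_ch, 0), dtype=np.float64)
    )
    return Recording(
        samples=samples,
        fs=float(meta["fs"]),
        subject_id=meta["subject_id"],
        day_index=int(meta["day_index"]),
        channel_names=channels,
    )


def _check_format(meta: dict, expected: str, path: str) -> None:
    tag = meta.get("format", "")
    parts = tag.rsplit(" v", 1)
    if len(parts) != 2 or parts[0] != expected:
        raise FormatError(f"{path}: not a {expected} file (format tag {tag!r})")
    major = int(parts[1].split(".")[0])
    if major != FORMAT_VERSION[0]:
        raise FormatError(
            f"{path}: unsupported major format version {major} "
            f"(reader supports {FORMAT_VERSION[0]})"
        )


# ---------------------------------------------------------------------------
# segment-dataset npz container
# ---------------------------------------------------------------------------

def write_segments(ds: SegmentDataset, path, overwrite: bool = True):
    """Write a segment dataset to an ``.npz`` container with JSON metadata."""
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    meta = json.dumps(
        {
            "format": SEGMENTS_FORMAT,
            "version": list(FORMAT_VERSION),
            "class_names": list(ds.class_names),
        }
    )
    np.savez(
        path,
        segments=ds.segments,
        labels=ds.labels,
        day_index=ds.day_index,
        rep_index=ds.rep_index,
        meta=np.array(meta),
    )
    return path


def read_segments(path) -> SegmentDataset:
    """Read a segment dataset written by :func:`write_segments`."""
    path = os.fspath(path)
    with np.load(path, allow_pickle=False) as z:
        try:
            meta = json.loads(str(z["meta"]))
        except KeyError as exc:
            raise FormatError(f"{path}: missing metadata blob") from exc
        if meta.get("format") != SEGMENTS_FORMAT:
            raise FormatError(f"{path}: not a {SEGMENTS_FORMAT} container")
        if meta.get("version", [0])[0] != FORMAT_VERSION[0]:
            raise FormatError(
                f"{path}: unsupported major format version {meta.get('version')}"
            )
        segments = z["segments"]
        labels = z["labels"]
        if segments.shape[0] != labels.shape[0]:
            raise FormatError(
                f"{path}: tensor holds {segments.shape[0]} segments but "
                f"{labels.shape[0]} labels"
            )
        return SegmentDataset(
            segments, labels, tuple(meta["class_names"]), z["day_index"], z["rep_index"]
        )


# ---------------------------------------------------------------------------
# experiment configs
# ---------------------------------------------------------------------------

def read_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from YAML or JSON."""
    with open(os.fspath(path)) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return ExperimentConfig.from_dict(data)


def write_config(cfg: ExperimentConfig, path):
    path = os.fspath(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    return path
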