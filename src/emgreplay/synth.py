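"""Multi-day synthetic sEMG study generator.

Stands in for a real multi-session acquisition: 12 daily sessions of 7
gesture classes x 100 repetitions, four channels at 1000 Hz. The signal
model is amplitude-modulated colored Gaussian noise — band-pass-filtered
white noise (20-300 Hz carrier by default), the standard surrogate for
interference-pattern EMG — shaped by a smooth on/off envelope and scaled per
channel by a gesture-specific mixing row (emulating muscle-specific
electrode placement). No motor-unit-level simulation: segmentation and
classification operate on envelope and channel pattern, not spike trains.

Two cross-session nuisance factors are modeled separately:

* **electrode displacement** — a small additive perturbation of the
  gesture-to-channel mixing matrix, resampled each day and compounded, so
  the distribution distance from day 1 grows with the day index;
* **time-varying amplitude drift** — a slow multiplicative gain trend
  per day.

Every generator is driven by an explicit integer seed: a (config, seed)
pair fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from emgreplay.io import Recording, SegmentDataset, DEFAULT_CHANNELS

GroundTruth = list[tuple[int, int, int]]  # (start, end, class), half-open


class GenerationError(RuntimeError):
    """Raised when a requested configuration cannot be realized."""


@dataclass
class ProtocolSpec:
    """Acquisition protocol: classes, repetitions, timing, sampling rate."""

    n_classes: int = 7
    reps_per_class: int = 100
    action_duration: tuple[int, int] = (600, 1400)  # samples, inclusive range
    rest_duration: tuple[int, int] = (300, 700)     # inter-action rest
    lead_in: tuple[int, int] = (1200, 1800)         # initial rest (baseline estimation)
    fs: float = 1000.0
    class_names: tuple[str, ...] = ("WE", "WF", "WRD", "WUD", "WS", "WP", "CF")

    def __post_init__(self) -> None:
        if self.reps_per_class <= 0 or self.n_classes <= 0:
            raise ValueError("n_classes and reps_per_class must be positive")
        if min(self.action_duration) <= 0 or min(self.rest_duration) <= 0:
            raise ValueError("durations must be positive")
        if len(self.class_names) < self.n_classes:
            self.class_names = tuple(f"G{i}" for i in range(self.n_classes))


@dataclass
class DriftModel:
    """Cross-session drift parameters.

    ``displacement_scale`` is the per-day standard deviation of the additive
    mixing-matrix perturbation (dimensionless, relative to max-normalized
    rows); ``daily_gain_drift`` is the multiplicative amplitude factor
    applied once per elapsed day. ``burst_band`` is the colored-noise
    carrier band in Hz.
    """

    displacement_scale: float = 0.25
    daily_gain_drift: float = 0.95
    rest_noise_sd: float = 0.05
    burst_noise_sd: float = 1.0
    burst_band: tuple[float, float] = (20.0, 300.0)
    amplitude_jitter: float = 0.1  # per-repetition lognormal-ish scale spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.displacement_scale < 0:
            raise ValueError("displacement_scale must be >= 0")
        if not self.burst_noise_sd > self.rest_noise_sd > 0:
            raise ValueError("need burst_noise_sd > rest_noise_sd > 0")

    def validate_band(self, fs: float) -> None:
        lo, hi = self.burst_band
        if not 0 < lo < hi < fs / 2:
            raise ValueError("burst_band must lie within (0, fs/2)")


def make_mixing_matrix(n_classes: int, n_channels: int, seed: int,
                       max_cosine: float = 0.95, max_tries: int = 200) -> np.ndarray:
    """Draw a gesture-to-channel activation matrix.

    Rows are non-negative and max-normalized to 1; pairwise row cosine
    similarity is kept below ``max_cosine`` so classes remain separable.
    """
    if n_classes < 1 or n_channels < 1:
        raise ValueError("n_classes and n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        # sparse-ish positive rows: one or two dominant channels per gesture
        m = rng.uniform(0.05, 0.4, size=(n_classes, n_channels))
        for c in range(n_classes):
            dom = rng.choice(n_channels, size=min(2, n_channels), replace=False)
            m[c, dom[0]] = rng.uniform(0.8, 1.0)
            if n_channels > 1:
                m[c, dom[1]] = rng.uniform(0.4, 0.9)
        m = m / m.max(axis=1, keepdims=True)
        if n_classes == 1 or _max_pairwise_cosine(m) < max_cosine:
            return m
    raise GenerationError(
        f"could not draw {n_classes} rows with pairwise cosine < {max_cosine} "
        f"in {max_tries} tries"
    )


def _max_pairwise_cosine(m: np.ndarray) -> float:
    norm = m / np.linalg.norm(m, axis=1, keepdims=True)
    cos = norm @ norm.T
    np.fill_diagonal(cos, -1.0)
    return float(cos.max())


def _normalize_rows(m: np.ndarray) -> np.ndarray:
    m = np.clip(m, 0.0, None)
    peaks = m.max(axis=1, keepdims=True)
    peaks[peaks == 0] = 1.0
    return m / peaks


def perturb_mixing(mixing: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    """One day of electrode displacement: additive noise, then re-normalize."""
    return _normalize_rows(mixing + rng.normal(0.0, scale, size=mixing.shape))


def day_mixing_sequence(mixing: np.ndarray, drift: DriftModel, n_days: int) -> list[np.ndarray]:
    """Per-day mixing matrices with compounding displacement (day 1 = input)."""
    rng = np.random.default_rng(np.random.SeedSequence([drift.seed, 0xD15]))
    out = [mixing]
    for _ in range(1, n_days):
        out.append(perturb_mixing(out[-1], drift.displacement_scale, rng))
    return out


def _colored_noise(n: int, band: tuple[float, float], fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    white = rng.standard_normal(n + 200)  # pad to absorb filter transients
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, white)[200:]
    sd = x.std()
    return x / sd if sd > 0 else x


def _envelope(n: int, ramp: int) -> np.ndarray:
    """Smooth on/off envelope: raised-cosine ramps over ``ramp`` samples."""
    ramp = min(ramp, n // 2)
    env = np.ones(n)
    if ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = r
        env[-ramp:] = r[::-1]
    return env


def generate_session(protocol: ProtocolSpec, mixing: np.ndarray, drift: DriftModel,
                     day: int, seed: int,
                     day_mixing: np.ndarray | None = None,
                     max_samples: int = 50_000_000) -> tuple[Recording, GroundTruth]:
    """Generate one day's continuous recording plus ground-truth intervals.

    Each of ``reps_per_class`` repetitions per class appears as a colored
    noise burst with a smooth envelope, scaled per channel by the day's
    (displacement-perturbed, gain-drifted) mixing row, separated by baseline
    rest noise. The ground truth is a sorted list of non-overlapping
    half-open (start, end, class) intervals.

    ``day_mixing`` overrides the internally derived day matrix (used by
    :func:`generate_study` to share one compounding perturbation sequence).
    """
    if day < 1:
        raise ValueError("day is 1-based and must be >= 1")
    drift.validate_band(protocol.fs)
    rng = np.random.default_rng(np.random.SeedSequence([seed, day]))
    if day_mixing is None:
        day_mixing = day_mixing_sequence(mixing, drift, day)[-1]
    gain = drift.daily_gain_drift ** (day - 1)

    # randomized repetition order, balanced per class
    order = np.repeat(np.arange(protocol.n_classes), protocol.reps_per_class)
    rng.shuffle(order)
    # per-class execution counter -> rep_index provenance
    n_actions = order.size
    durations = rng.integers(protocol.action_duration[0],
                             protocol.action_duration[1] + 1, size=n_actions)
    rests = rng.integers(protocol.rest_duration[0],
                         protocol.rest_duration[1] + 1, size=n_actions)
    lead = int(rng.integers(protocol.lead_in[0], protocol.lead_in[1] + 1))
    total = lead + int(durations.sum() + rests.sum()) + 500
    if total > max_samples:
        raise GenerationError(
            f"session would span {total} samples (> {max_samples} guard)"
        )
    n_ch = mixing.shape[1]
    x = rng.normal(0.0, drift.rest_noise_sd, size=(n_ch, total))
    truth: GroundTruth = []
    pos = lead
    for a in range(n_actions):
        cls = int(order[a])
        dur = int(durations[a])
        burst = _colored_noise(dur, drift.burst_band, protocol.fs, rng)
        env = _envelope(dur, ramp=100)
        amp = drift.burst_noise_sd * gain * np.exp(
            rng.normal(0.0, drift.amplitude_jitter)
        )
        for ch in range(n_ch):
            x[ch, pos : pos + dur] += amp * day_mixing[cls, ch] * burst * env
        truth.append((pos, pos + dur, cls))
        pos += dur + int(rests[a])
    rec = Recording(
        samples=x[:, :pos + 400],
        fs=protocol.fs,
        subject_id="synthetic",
        day_index=day,
        channel_names=DEFAULT_CHANNELS[:n_ch],
    )
    return rec, truth


@dataclass
class Study:
    """A multi-day synthetic study with its ground truth and drift trace."""

    recordings: list[Recording]
    ground_truths: list[GroundTruth]
    day_mixings: list[np.ndarray]
    protocol: ProtocolSpec
    drift: DriftModel


def generate_study(n_days: int, protocol: ProtocolSpec, drift: DriftModel,
                   seed: int) -> Study:
    """Generate ``n_days`` sessions sharing one compounding drift trajectory."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    mixing = make_mixing_matrix(protocol.n_classes, 4, seed=drift.seed)
    mixings = day_mixing_sequence(mixing, drift, n_days)
    recordings, truths = [], []
    for day in range(1, n_days + 1):
        rec, truth = generate_session(
            protocol, mixing, drift, day, seed, day_mixing=mixings[day - 1]
        )
        recordings.append(rec)
        truths.append(truth)
    return Study(recordings, truths, mixings, protocol, drift)


# ---------------------------------------------------------------------------
# direct segment synthesis (ground-truth boundaries, no detection step)
# ---------------------------------------------------------------------------

def segments_from_session(rec: Recording, truth: GroundTruth,
                          class_names: tuple[str, ...],
                          target_length: int = 1000) -> SegmentDataset:
    """Cut a session at its ground-truth boundaries into labeled segments.

    Windows are standardized to ``target_length`` samples centered on each
    interval's midpoint (flanking raw signal is included when the interval
    is shorter; edges are clamped), mirroring the segmentation stage's
    standardization policy.
    """
    from emgreplay.preprocess import standardize_window  # local import: no cycle at module load

    segs, labels, reps = [], [], []
    counters = dict.fromkeys(range(len(class_names)), 0)
    for start, end, cls in truth:
        segs.append(standardize_window(rec.samples, start, end, target_length))
        labels.append(cls)
        reps.append(counters[cls])
        counters[cls] += 1
    n = len(segs)
    return SegmentDataset(
        np.stack(segs) if n else np.zeros((0, rec.n_channels, target_length)),
        np.array(labels, dtype=np.int64),
        class_names,
        np.full(n, rec.day_index, dtype=np.int64),
        np.array(reps, dtype=np.int64),
    )


def generate_labeled_study(n_days: int, protocol: ProtocolSpec, drift: DriftModel,
                           seed: int) -> list[SegmentDataset]:
    """One labeled :class:`SegmentDataset` per day, cut at ground truth."""
    study = generate_study(n_days, protocol, drift, seed)
    return [
        segments_from_session(rec, truth, protocol.class_names[: protocol.n_classes])
        for rec, truth in zip(study.recordings, study.ground_truths)
    ]
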