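"""Shared fixtures: tiny synthetic datasets and scaled-down model specs.

Heavy multi-day studies are session-scoped so the generation cost is paid
once; training-based tests use the reduced architecture and short segment
lengths where the full 1000-sample protocol length is not the property
under test.
"""

from __future__ import annotations

import numpy as np
import pytest

from emgreplay import synth
from emgreplay.densenet import DenseNetSpec, TrainConfig
from emgreplay.io import SegmentDataset


def make_toy_dataset(n_per_class: int, n_classes: int = 2, length: int = 100,
                     n_channels: int = 4, seed: int = 0) -> SegmentDataset:
    """Separable-by-construction segments: distinct noise amplitude per class."""
    rng = np.random.default_rng(seed)
    segs, labels, reps = [], [], []
    for c in range(n_classes):
        amp = 0.3 + 0.8 * c
        for r in range(n_per_class):
            segs.append(rng.normal(0.0, amp, size=(n_channels, length)))
            labels.append(c)
            reps.append(r)
    return SegmentDataset(
        np.stack(segs), np.array(labels), tuple(f"G{i}" for i in range(n_classes)),
        np.ones(len(labels), dtype=np.int64), np.array(reps),
    )


@pytest.fixture(scope="session")
def toy_spec():
    """A miniature DenseNet for mechanics tests on short 100-sample segments."""
    return DenseNetSpec(
        growth_rate=8, block_sizes=(2, 2), stem_channels=16,
        n_classes=2, input_length=100,
    )


@pytest.fixture(scope="session")
def fast_cfg():
    return TrainConfig(epochs=10, batch_size=16, seed=0, val_fraction=0.2)


@pytest.fixture(scope="session")
def small_protocol():
    return synth.ProtocolSpec(reps_per_class=10)


@pytest.fixture(scope="session")
def default_drift():
    return synth.DriftModel(seed=0)


@pytest.fixture(scope="session")
def small_session(small_protocol, default_drift):
    """One synthetic day: (Recording, ground truth), 70 actions."""
    mixing = synth.make_mixing_matrix(7, 4, seed=0)
    return synth.generate_session(small_protocol, mixing, default_drift, day=1, seed=5)


@pytest.fixture(scope="session")
def labeled_study_3day():
    """3 days x 7 classes x 12 reps of labeled segments (default drift)."""
    proto = synth.ProtocolSpec(reps_per_class=12)
    return synth.generate_labeled_study(3, proto, synth.DriftModel(seed=0), seed=11)
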