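"""1-D densely connected CNN classifier for standardized sEMG segments.

The network follows the DenseNet pattern adapted to one temporal dimension:
a stem (conv k7/s2 -> BN -> ReLU -> max-pool 3/s2), four dense blocks of six
plain composite layers (BN -> ReLU -> conv k3, growth rate 24, no bottleneck),
transition layers (BN -> ReLU -> 1x1 conv with compression 0.5 -> average
pool /2) between blocks, then BN -> ReLU -> global average pooling and a
linear head. Within a block, layer ``j`` consumes the channel-concatenation
of the block input and all previous layer outputs, so its input width is
``entry_channels + j * growth_rate``.

With the default spec this lands at ~0.37 M trainable parameters (0.4 M at
one decimal), an order of magnitude leaner than image-scale CNNs. The
bottleneck-free composite is what pins that budget: a 1x1-bottleneck variant
lands near 0.6 M.

Convolutions are bias-free (batch norm absorbs the bias). The optimizer is
Adam at the protocol learning rate 0.001.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from emgreplay import nn
from emgreplay.io import SegmentDataset


@dataclass
class DenseNetSpec:
    """Full hyperparameter description of the 1-D DenseNet."""

    growth_rate: int = 24
    block_sizes: tuple[int, ...] = (6, 6, 6, 6)
    compression: float = 0.5
    stem_channels: int = 48
    stem_kernel: int = 7
    stem_stride: int = 2
    stem_pool: int = 3
    stem_pool_stride: int = 2
    dense_kernel: int = 3
    n_classes: int = 7
    input_channels: int = 4
    input_length: int = 1000

    def __post_init__(self) -> None:
        self.block_sizes = tuple(int(b) for b in self.block_sizes)
        ints = (self.growth_rate, *self.block_sizes, self.stem_channels,
                self.stem_kernel, self.stem_stride, self.stem_pool,
                self.stem_pool_stride, self.dense_kernel, self.n_classes,
                self.input_channels, self.input_length)
        if any(v <= 0 for v in ints):
            raise ValueError("all DenseNetSpec sizes must be positive")
        if not 0.0 < self.compression <= 1.0:
            raise ValueError("compression must lie in (0, 1]")

    @staticmethod
    def reduced(n_classes: int = 7) -> "DenseNetSpec":
        """A scaled-down spec (blocks 3-3, growth 12, stem stride 4) for
        small-sample desk-scale studies; same architecture family."""
        return DenseNetSpec(
            growth_rate=12, block_sizes=(3, 3), stem_channels=24,
            stem_stride=4, n_classes=n_classes,
        )

    def channel_plan(self) -> list[dict]:
        """Closed-form channel bookkeeping per block.

        Returns one dict per dense block with the entry channel count, the
        per-layer input widths ``entry + j * growth_rate``, the block exit
        width, and the post-transition width (``floor(exit * compression)``;
        the last block has no transition).
        """
        plan = []
        ch = self.stem_channels
        for b, n_layers in enumerate(self.block_sizes):
            entry = ch
            layer_in = [entry + j * self.growth_rate for j in range(n_layers)]
            exit_ch = entry + n_layers * self.growth_rate
            if b < len(self.block_sizes) - 1:
                ch = int(exit_ch * self.compression)
            else:
                ch = exit_ch
            plan.append({"entry": entry, "layer_in": layer_in,
                         "exit": exit_ch, "after_transition": ch})
        return plan


@dataclass
class TrainConfig:
    """Training protocol parameters (defaults follow the study protocol)."""

    lr: float = 0.001
    epochs: int = 50
    batch_size: int = 128
    val_fraction: float = 0.2
    seed: int = 0
    patience: int | None = None

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")


class _DenseLayer(nn.Module):
    """Plain composite BN -> ReLU -> conv(k=3, pad 1); adds growth_rate channels."""

    def __init__(self, in_ch: int, growth: int, kernel: int, rng):
        self.bn = nn.BatchNorm1d(in_ch)
        self.relu = nn.ReLU()
        self.conv = nn.Conv1d(in_ch, growth, kernel, padding=kernel // 2, rng=rng)

    def parameters(self):
        return self.bn.parameters() + self.conv.parameters()

    def forward(self, x, train):
        return self.conv.forward(self.relu.forward(self.bn.forward(x, train), train), train)

    def backward(self, g):
        return self.bn.backward(self.relu.backward(self.conv.backward(g)))


class _DenseBlock(nn.Module):
    def __init__(self, in_ch: int, n_layers: int, growth: int, kernel: int, rng):
        self.layers = [
            _DenseLayer(in_ch + j * growth, growth, kernel, rng)
            for j in range(n_layers)
        ]
        self.in_ch, self.growth = in_ch, growth

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x, train):
        feats = [x]
        for layer in self.layers:
            feats.append(layer.forward(np.concatenate(feats, axis=1), train))
        self._widths = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, g):
        bounds = np.cumsum([0] + self._widths)
        # gradient accumulator per concatenated feature slab
        accs = [np.ascontiguousarray(g[:, bounds[i] : bounds[i + 1]])
                for i in range(len(self._widths))]
        for j in range(len(self.layers) - 1, -1, -1):
            gin = self.layers[j].backward(accs[j + 1])
            sub = np.cumsum([0] + self._widths[: j + 1])
            for i in range(j + 1):
                accs[i] += gin[:, sub[i] : sub[i + 1]]
        return accs[0]


class _Transition(nn.Module):
    """BN -> ReLU -> 1x1 conv (compression) -> average pool /2."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        self.bn = nn.BatchNorm1d(in_ch)
        self.relu = nn.ReLU()
        self.conv = nn.Conv1d(in_ch, out_ch, 1, rng=rng)
        self.pool = nn.AvgPool1d(2)

    def parameters(self):
        return self.bn.parameters() + self.conv.parameters()

    def forward(self, x, train):
        x = self.relu.forward(self.bn.forward(x, train), train)
        return self.pool.forward(self.conv.forward(x, train), train)

    def backward(self, g):
        g = self.conv.backward(self.pool.backward(g))
        return self.bn.backward(self.relu.backward(g))


class DenseNet1d(nn.Module):
    """The assembled classifier: maps (B, channels, length) to (B, n_classes) logits."""

    def __init__(self, spec: DenseNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.stem_conv = nn.Conv1d(
            spec.input_channels, spec.stem_channels, spec.stem_kernel,
            stride=spec.stem_stride, padding=spec.stem_kernel // 2, rng=rng,
        )
        self.stem_bn = nn.BatchNorm1d(spec.stem_channels)
        self.stem_relu = nn.ReLU()
        self.stem_pool = nn.MaxPool1d(
            spec.stem_pool, spec.stem_pool_stride, padding=spec.stem_pool // 2
        )
        self.blocks: list[_DenseBlock] = []
        self.transitions: list[_Transition] = []
        ch = spec.stem_channels
        for b, n_layers in enumerate(spec.block_sizes):
            block = _DenseBlock(ch, n_layers, spec.growth_rate, spec.dense_kernel, rng)
            self.blocks.append(block)
            ch += n_layers * spec.growth_rate
            if b < len(spec.block_sizes) - 1:
                out = int(ch * spec.compression)
                self.transitions.append(_Transition(ch, out, rng))
                ch = out
        self.final_bn = nn.BatchNorm1d(ch)
        self.final_relu = nn.ReLU()
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Linear(ch, spec.n_classes, rng=rng)
        self.feature_dim = ch

    @property
    def n_classes(self) -> int:
        return self.head.w.data.shape[0]

    def _ordered_modules(self) -> list[nn.Module]:
        mods: list[nn.Module] = [self.stem_conv, self.stem_bn]
        for b, block in enumerate(self.blocks):
            for layer in block.layers:
                mods.extend([layer.bn, layer.conv])
            if b < len(self.transitions):
                mods.extend([self.transitions[b].bn, self.transitions[b].conv])
        mods.extend([self.final_bn, self.head])
        return mods

    def parameters(self):
        return [p for m in self._ordered_modules() for p in m.parameters()]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        x = self.stem_conv.forward(x, train)
        x = self.stem_relu.forward(self.stem_bn.forward(x, train), train)
        x = self.stem_pool.forward(x, train)
        for b, block in enumerate(self.blocks):
            x = block.forward(x, train)
            if b < len(self.transitions):
                x = self.transitions[b].forward(x, train)
        x = self.final_relu.forward(self.final_bn.forward(x, train), train)
        return self.head.forward(self.gap.forward(x, train), train)

    def backward(self, dlogits):
        g = self.gap.backward(self.head.backward(dlogits))
        g = self.final_bn.backward(self.final_relu.backward(g))
        for b in range(len(self.blocks) - 1, -1, -1):
            if b < len(self.transitions):
                g = self.transitions[b].backward(g)
            g = self.blocks[b].backward(g)
        g = self.stem_pool.backward(g)
        g = self.stem_bn.backward(self.stem_relu.backward(g))
        return self.stem_conv.backward(g)

    # -- state (de)serialization ------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays: list[np.ndarray] = []
        for m in self._ordered_modules():
            for p in m.parameters():
                arrays.append(p.data)
            if isinstance(m, nn.BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for m in self._ordered_modules():
            for p in m.parameters():
                a = next(it)
                if a.shape != p.data.shape:
                    raise ValueError("checkpoint shape mismatch")
                p.data = np.ascontiguousarray(a, dtype=np.float32)
            if isinstance(m, nn.BatchNorm1d):
                m.running_mean = np.ascontiguousarray(next(it), dtype=np.float32)
                m.running_var = np.ascontiguousarray(next(it), dtype=np.float32)

    def copy(self) -> "DenseNet1d":
        clone = DenseNet1d(self.spec, seed=0)
        if self.n_classes != clone.n_classes:  # an expanded head
            clone.head = nn.Linear(self.feature_dim, self.n_classes)
        clone.load_state_arrays([a.copy() for a in self.state_arrays()])
        return clone


def build_model(spec: DenseNetSpec, seed: int = 0) -> DenseNet1d:
    """Instantiate the classifier with seeded weight initialization."""
    return DenseNet1d(spec, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Total trainable scalar parameters (batch-norm running stats excluded)."""
    return int(sum(p.data.size for p in model.parameters()))


def save_model(model: DenseNet1d, path, class_names: tuple[str, ...] = ()):
    """Save spec + weights + class names in one ``.npz`` container."""
    meta = json.dumps({
        "spec": asdict(model.spec),
        "n_classes_actual": model.n_classes,
        "class_names": list(class_names),
    })
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(os.fspath(path), meta=np.array(meta), **arrays)
    return path


def load_model(path) -> tuple[DenseNet1d, tuple[str, ...]]:
    with np.load(os.fspath(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        spec_d = dict(meta["spec"])
        spec_d["block_sizes"] = tuple(spec_d["block_sizes"])
        spec = DenseNetSpec(**spec_d)
        model = DenseNet1d(spec, seed=0)
        if meta["n_classes_actual"] != spec.n_classes:
            model.head = nn.Linear(model.feature_dim, meta["n_classes_actual"])
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    model.load_state_arrays(arrays)
    return model, tuple(meta["class_names"])


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _stratified_split(labels: np.ndarray, val_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * idx.size))
        if idx.size - n_val < 1:  # never empty the training side
            n_val = max(idx.size - 1, 0)
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def evaluate_loss_acc(model: DenseNet1d, x: np.ndarray, y: np.ndarray,
                      batch_size: int = 256) -> tuple[float, float]:
    """Eval-mode mean cross-entropy and accuracy on (x, y)."""
    losses, correct = [], 0
    for s in range(0, len(x), batch_size):
        logits = model.forward(x[s : s + batch_size], train=False)
        loss, _ = nn.softmax_cross_entropy(logits, y[s : s + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[s : s + batch_size]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(model: DenseNet1d, train_set: SegmentDataset, cfg: TrainConfig):
    """Train with minibatch Adam on cross-entropy; returns (model, history).

    A stratified ``val_fraction`` share of the data is held out per epoch for
    monitoring (and optional early stopping via ``cfg.patience``); the model
    is fit on the remainder. ``epochs=0`` returns the model unchanged with an
    empty history. Fully seeded: a fixed (initial weights, data, config) is
    bit-reproducible.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    if int(train_set.labels.max()) >= model.n_classes:
        raise ValueError(
            f"label {int(train_set.labels.max())} outside the model's "
            f"{model.n_classes} classes"
        )
    history: dict[str, list] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    if cfg.epochs == 0:
        return model, history

    rng = np.random.default_rng(cfg.seed)
    x = np.ascontiguousarray(train_set.segments, dtype=np.float32)
    y = train_set.labels
    if cfg.val_fraction > 0:
        tr_idx, va_idx = _stratified_split(y, cfg.val_fraction, rng)
    else:
        tr_idx, va_idx = np.arange(len(y)), np.zeros(0, dtype=np.int64)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    best_val, since_best = -np.inf, 0
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(tr_idx)
        ep_loss, ep_correct = 0.0, 0
        for s in range(0, len(perm), cfg.batch_size):
            bidx = perm[s : s + cfg.batch_size]
            logits = model.forward(x[bidx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[bidx])
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(bidx)
            ep_correct += int((logits.argmax(axis=1) == y[bidx]).sum())
        history["train_loss"].append(ep_loss / len(perm))
        history["train_acc"].append(ep_correct / len(perm))
        if va_idx.size:
            vl, va = evaluate_loss_acc(model, x[va_idx], y[va_idx])
            history["val_loss"].append(vl)
            history["val_acc"].append(va)
            if cfg.patience is not None:
                if va > best_val:
                    best_val, since_best = va, 0
                else:
                    since_best += 1
                    if since_best >= cfg.patience:
                        break
    return model, history


def predict(model: DenseNet1d, segs, batch_size: int = 256):
    """Predict class ids and row-normalized probabilities.

    ``segs`` may be a :class:`SegmentDataset` or a raw array of shape
    ``(n, channels, length)``. Eval-mode batch norm makes the output
    invariant to how the input is partitioned into batches.
    """
    x = segs.segments if isinstance(segs, SegmentDataset) else np.asarray(segs)
    spec = model.spec
    if x.ndim != 3 or x.shape[1] != spec.input_channels or x.shape[2] != spec.input_length:
        raise ValueError(
            f"expected segments shaped (n, {spec.input_channels}, "
            f"{spec.input_length}), got {x.shape}"
        )
    if len(x) == 0:
        return np.zeros(0, dtype=np.int64), np.zeros((0, model.n_classes))
    probs = []
    for s in range(0, len(x), batch_size):
        logits = model.forward(x[s : s + batch_size], train=False)
        probs.append(nn.softmax(logits))
    p = np.concatenate(probs)
    return p.argmax(axis=1).astype(np.int64), p
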