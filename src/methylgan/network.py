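"""Stage-1 convolutional classifier: architecture, training, inference.

The classifier consumes one-hot encoded 41-bp windows (length-major layout,
shape ``(n, l, 4)``) and scores the central adenine's methylation probability.
It is five convolutional blocks — each a valid 1-D cross-correlation along
the sequence, a LeakyReLU, and dropout — followed by two fully connected
hidden layers and a sigmoid output.  Training minimizes binary cross-entropy
with Adam and early-stops on validation ROC-AUC: a checkpoint is kept only
when the validation AUC strictly improves, and the best checkpoint (not the
last epoch) is returned.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .metrics import roc_auc
from .seqio import SequenceRecord, DatasetSplit, encode_batch, subset


# ---------------------------------------------------------------------------
# architecture specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvBlockSpec:
    """One convolutional block: kernel height along the sequence, number of
    filters, dropout rate.  The kernel width always spans every incoming
    channel (valid cross-correlation consumes the full channel axis)."""

    kernel_size: int
    filters: int
    dropout: float

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.kernel_size < 1 or self.filters < 1:
            raise ValueError("kernel size and filter count must be positive")


@dataclass(frozen=True)
class NetworkSpec:
    """Full classifier architecture.  Exactly five conv blocks."""

    conv_blocks: tuple[ConvBlockSpec, ...]
    leaky_slope: float = 0.01
    fc_widths: tuple[int, int] = (128, 32)
    input_shape: tuple[int, int] = (4, 41)  # (channels, length)

    def __post_init__(self):
        blocks = tuple(b if isinstance(b, ConvBlockSpec) else ConvBlockSpec(*b)
                       for b in self.conv_blocks)
        object.__setattr__(self, "conv_blocks", blocks)
        if len(blocks) != 5:
            raise ValueError("the architecture has exactly five conv blocks")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ValueError("LeakyReLU slope must lie in (0, 1)")
        # check kernels fit
        L = self.input_shape[1]
        for i, b in enumerate(blocks, 1):
            L = L - b.kernel_size + 1
            if L < 1:
                raise ValueError(f"conv block {i} kernel does not fit input")

    def block_output_shape(self, block_index: int) -> tuple[int, int]:
        """(channels, positions) of the given block's output (1-based)."""
        L = self.input_shape[1]
        for b in self.conv_blocks[:block_index]:
            L = L - b.kernel_size + 1
        return (self.conv_blocks[block_index - 1].filters, L)

    @property
    def flat_dim(self) -> int:
        c, p = self.block_output_shape(5)
        return c * p


def default_spec(l: int = 41) -> NetworkSpec:
    """Reference architecture: filter counts (32, 64, 128, 128, 128), kernel
    height 5, dropout 0.3, slope 0.01, FC widths (128, 32)."""
    return NetworkSpec(
        conv_blocks=tuple(ConvBlockSpec(5, f, 0.3) for f in (32, 64, 128, 128, 128)),
        leaky_slope=0.01, fc_widths=(128, 32), input_shape=(4, l))


def compact_spec(l: int = 41) -> NetworkSpec:
    """Reduced-width architecture for CPU-minute experiments and tests:
    filter counts (8, 16, 16, 16, 16), FC widths (32, 16)."""
    return NetworkSpec(
        conv_blocks=tuple(ConvBlockSpec(5, f, 0.3) for f in (8, 16, 16, 16, 16)),
        leaky_slope=0.01, fc_widths=(32, 16), input_shape=(4, l))


# ---------------------------------------------------------------------------
# primitive ops (also exposed standalone for direct use/verification)
# ---------------------------------------------------------------------------

def conv_valid(X: np.ndarray, W: np.ndarray,
               bias: np.ndarray | None = None) -> np.ndarray:
    """Valid cross-correlation of one input against a bank of kernels.

    ``X`` is (H, width); ``W`` is (filters, M, N) with M <= H and N <= width.
    Output (filters, H - M + 1)::

        out[f, i] = sum_{m<M} sum_{n<N} W[f, m, n] * X[i + m, n]  (+ bias[f])

    The column index is absolute (no horizontal sliding): the kernel width
    consumes the first N columns, which in the network equals the full
    channel axis.  No kernel flip — this is correlation, not convolution in
    the signal-processing sense.
    """
    X = np.asarray(X, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    F, M, N = W.shape
    H, width = X.shape
    if M > H or N > width:
        raise ValueError(f"kernel {M}x{N} does not fit input {H}x{width}")
    out = ad.conv1d(Tensor(X[None, :, :N]), Tensor(W)).data[0].T  # (F, H-M+1)
    if bias is not None:
        out = out + np.asarray(bias, dtype=np.float64)[:, None]
    return out


def activate(x, kind: str, a: float = 0.01) -> np.ndarray:
    """LeakyReLU (x if x >= 0 else a*x) or the logistic sigmoid."""
    x = np.asarray(x, dtype=np.float64)
    if kind == "leaky_relu":
        if a <= 0:
            raise ValueError("LeakyReLU slope must be positive")
        return np.where(x >= 0, x, a * x)
    if kind == "sigmoid":
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-x))
    raise ValueError(f"unknown activation kind {kind!r}")


# ---------------------------------------------------------------------------
# model state
# ---------------------------------------------------------------------------

_LAYERS = ("conv_1", "conv_2", "conv_3", "conv_4", "conv_5", "fc_1", "fc_2", "out")


@dataclass
class ModelState:
    """Named parameters of the classifier plus per-layer trainable flags."""

    spec: NetworkSpec
    params: dict[str, dict[str, np.ndarray]]
    trainable: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if not self.trainable:
            self.trainable = {name: True for name in self.params}

    def copy(self) -> "ModelState":
        return ModelState(self.spec,
                          {k: {kk: vv.copy() for kk, vv in v.items()}
                           for k, v in self.params.items()},
                          dict(self.trainable))

    # -- persistence: .npz arrays + JSON manifest --------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"{name}.{part}": arr
                  for name, layer in self.params.items()
                  for part, arr in layer.items()}
        np.savez(path, **arrays)
        manifest = {
            "conv_blocks": [[b.kernel_size, b.filters, b.dropout]
                            for b in self.spec.conv_blocks],
            "leaky_slope": self.spec.leaky_slope,
            "fc_widths": list(self.spec.fc_widths),
            "input_shape": list(self.spec.input_shape),
            "trainable": self.trainable,
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        spec = NetworkSpec(
            conv_blocks=tuple(ConvBlockSpec(int(k), int(f), float(d))
                              for k, f, d in manifest["conv_blocks"]),
            leaky_slope=manifest["leaky_slope"],
            fc_widths=tuple(manifest["fc_widths"]),
            input_shape=tuple(manifest["input_shape"]))
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        params: dict[str, dict[str, np.ndarray]] = {}
        for key in data.files:
            name, part = key.rsplit(".", 1)
            params.setdefault(name, {})[part] = data[key]
        return cls(spec, params, dict(manifest["trainable"]))


def init_params(spec: NetworkSpec, rng: np.random.Generator) -> dict:
    """He-style initialization sized from fan-in; biases start at zero."""
    params: dict[str, dict[str, np.ndarray]] = {}
    c_in = spec.input_shape[0]
    for i, b in enumerate(spec.conv_blocks, 1):
        fan_in = b.kernel_size * c_in
        params[f"conv_{i}"] = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(b.filters, b.kernel_size, c_in)),
            "b": np.zeros(b.filters),
        }
        c_in = b.filters
    d = spec.flat_dim
    widths = (d, *spec.fc_widths, 1)
    for j, name in enumerate(("fc_1", "fc_2", "out")):
        params[name] = {
            "W": rng.normal(0.0, np.sqrt(2.0 / widths[j]),
                            size=(widths[j], widths[j + 1])),
            "b": np.zeros(widths[j + 1]),
        }
    return params


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _dropout(h: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    if rate <= 0.0:
        return h
    mask = (rng.random(h.shape) >= rate) / (1.0 - rate)  # inverted dropout
    return ad.mul(h, Tensor(mask))


def forward_logits(state: ModelState, X, *, train: bool = False,
                   rng: np.random.Generator | None = None,
                   params: dict[str, Tensor] | None = None,
                   upto_block: int | None = None,
                   from_block: int = 1) -> Tensor:
    """Run the network, returning pre-sigmoid logits of shape (n, 1).

    ``params`` may supply Tensor-wrapped parameters (used during training so
    gradients flow); otherwise the state's arrays are used as constants.
    ``upto_block`` returns the post-activation output of that block (n,
    positions, channels) instead of logits; ``from_block`` starts the pass at
    the given block's convolution, for injecting feature maps mid-network.
    Dropout is applied only when ``train`` is true, and only in blocks that
    actually run.
    """
    spec = state.spec
    if train and rng is None:
        raise ValueError("training-mode forward needs an RNG for dropout")

    def P(name, part):
        if params is not None and f"{name}.{part}" in params:
            return params[f"{name}.{part}"]
        return Tensor(state.params[name][part])

    h = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=np.float64))
    if h.ndim != 3:
        raise ValueError("input must be (n, length, channels)")
    for i in range(from_block, 6):
        name = f"conv_{i}"
        block = spec.conv_blocks[i - 1]
        expect_c = spec.input_shape[0] if i == 1 else spec.conv_blocks[i - 2].filters
        if h.shape[2] != expect_c:
            raise ValueError(f"block {i} expects {expect_c} channels, "
                             f"got {h.shape[2]}")
        h = ad.add(ad.conv1d(h, P(name, "W")), P(name, "b"))
        h = ad.leaky_relu(h, spec.leaky_slope)
        if upto_block == i:
            return h
        if train:
            h = _dropout(h, block.dropout, rng)
    # flatten channel-major: (n, L, C) -> (n, C, L) -> (n, C*L)
    n = h.shape[0]
    h = ad.reshape(ad.transpose(h, (0, 2, 1)), (n, -1))
    for name in ("fc_1", "fc_2"):
        h = ad.leaky_relu(ad.add(ad.matmul(h, P(name, "W")), P(name, "b")),
                          spec.leaky_slope)
    return ad.add(ad.matmul(h, P("out", "W")), P("out", "b"))


def predict_proba(state: ModelState, X) -> np.ndarray:
    """Methylation-probability scores in (0, 1), one per input row.

    Deterministic: dropout is disabled at inference.
    """
    logits = forward_logits(state, X, train=False).data[:, 0]
    return activate(logits, "sigmoid")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class TrainingHistory:
    val_auc: list[float]
    best_epoch: int  # 1-based; first epoch attaining the maximum val AUC
    checkpoint_path: str | None = None
    train_pool_size: int | None = None  # fine-tuning: real + synthetic rows


def _bce_from_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    yt = Tensor(y[:, None])
    pos = ad.mul(yt, ad.logsigmoid(logits))
    neg = ad.mul(1.0 - yt, ad.logsigmoid(ad.mul(logits, -1.0)))
    return ad.mul(ad.tmean(ad.add(pos, neg)), -1.0)


def _sgd_epochs(state: ModelState, trainable_names: list[str],
                batches_fn, val_fn, config: TrainingConfig,
                rng: np.random.Generator, learning_rate: float,
                from_block: int = 1) -> TrainingHistory:
    """Shared early-stopping training loop used by stage 1 and fine-tuning.

    ``batches_fn(rng)`` yields (X_batch, y_batch) covering one epoch;
    ``val_fn(state)`` returns the validation AUC of the current state.
    Mutates ``state`` in place to the best checkpoint and returns its history.
    The trainable parameters are wrapped as autodiff leaves aliasing the
    state's arrays, so optimizer steps update the state directly.
    """
    tensors = {f"{n}.{p}": Tensor(state.params[n][p], requires_grad=True)
               for n in trainable_names for p in ("W", "b")}
    opt = ad.Adam(tensors, lr=learning_rate)
    best_auc = -np.inf
    best_epoch = 0
    best_params = None
    history: list[float] = []
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        for Xb, yb in batches_fn(rng):
            logits = forward_logits(state, Xb, train=True, rng=rng,
                                    params=tensors, from_block=from_block)
            loss = _bce_from_logits(logits, yb)
            grads = ad.grad(loss, list(tensors.values()))
            opt.step({k: g.data for k, g in zip(tensors, grads)})
        auc = val_fn(state)
        history.append(auc)
        if auc > best_auc:  # strict improvement refreshes the checkpoint
            best_auc = auc
            best_epoch = epoch
            best_params = {n: {p: state.params[n][p].copy() for p in ("W", "b")}
                           for n in state.params}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_params is not None:
        state.params = best_params
    return TrainingHistory(val_auc=history, best_epoch=best_epoch)


def _check_val_labels(y_val: np.ndarray) -> None:
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation set must contain both classes "
                         "(AUC is undefined otherwise)")


def train_stage1(records: list[SequenceRecord], split: DatasetSplit,
                 spec: NetworkSpec, config: TrainingConfig
                 ) -> tuple[ModelState, TrainingHistory]:
    """Train the base classifier with validation-AUC early stopping.

    Returns the best-validation checkpoint (never the final epoch) and the
    per-epoch validation AUC trace.  Fully deterministic given
    ``config.seed``.
    """
    train_recs = subset(records, split.train_ids)
    val_recs = subset(records, split.val_ids)
    if not train_recs or not val_recs:
        raise ValueError("train and validation sets must be non-empty")
    X_tr, y_tr = encode_batch(train_recs)
    X_va, y_va = encode_batch(val_recs)
    _check_val_labels(y_va)

    master = np.random.SeedSequence(config.seed)
    init_rng, loop_rng = (np.random.default_rng(s) for s in master.spawn(2))
    state = ModelState(spec, init_params(spec, init_rng))

    def batches(rng):
        order = rng.permutation(len(X_tr))
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            yield X_tr[idx], y_tr[idx]

    def val_auc(st):
        return roc_auc(y_va.astype(int), predict_proba(st, X_va))[0]

    history = _sgd_epochs(state, list(_LAYERS), batches, val_auc,
                          config, loop_rng, config.learning_rate)
    return state, history
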