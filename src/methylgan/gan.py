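"""Intermediate-feature extraction and per-class WGAN-GP feature synthesis.

After the base classifier is trained, the post-activation output of an
intermediate convolutional block (default: block 3) is flattened
channel-major into feature vectors.  One Wasserstein GAN with gradient
penalty is trained per class on those vectors — positives and negatives are
never mixed, so each generator models a single class-conditional feature
distribution.  Generator checkpoints are emitted on a fixed epoch interval;
checkpoint quality is judged downstream by a classifier two-sample test.

The critic maximizes  E[D(x_real)] - E[D(G(z))] - lambda * GP  where the
gradient penalty GP pushes the critic's gradient norm at random
real/fake interpolates toward 1.  Generator and critic are 3-layer fully
connected networks with LeakyReLU hidden activations; the generator output
is linear, since post-LeakyReLU features are unbounded reals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .network import ModelState, forward_logits
from .seqio import SequenceRecord, encode_batch

#: LeakyReLU slope used inside GAN networks (standard GAN practice)
_GAN_SLOPE = 0.2


# ---------------------------------------------------------------------------
# feature containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureBatch:
    """n x d matrix of flattened feature vectors with provenance."""

    values: np.ndarray            # (n, d) float
    labels: np.ndarray            # (n,) 0/1 class labels
    source: np.ndarray            # (n,) "real" | "synthetic"
    layer_shape: tuple[int, int]  # (channels, positions), channels*positions == d

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.source = np.asarray(self.source)
        c, p = self.layer_shape
        if self.values.ndim != 2 or self.values.shape[1] != c * p:
            raise ValueError(f"values must be (n, {c * p}) for layer_shape "
                             f"{self.layer_shape}")
        if not (len(self.labels) == len(self.source) == len(self.values)):
            raise ValueError("values, labels and source must align")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def restrict(self, label: int) -> "FeatureBatch":
        m = self.labels == label
        return FeatureBatch(self.values[m], self.labels[m], self.source[m],
                            self.layer_shape)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, values=self.values, labels=self.labels,
                 source=self.source)
        path.with_suffix(".json").write_text(json.dumps(
            {"layer_shape": list(self.layer_shape)}))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureBatch":
        path = Path(path)
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(data["values"], data["labels"], data["source"],
                   tuple(meta["layer_shape"]))


def extract_features(model: ModelState, records: list[SequenceRecord],
                     block_index: int = 3) -> FeatureBatch:
    """Flattened post-activation features of the given conv block.

    Each record is forward-passed through blocks 1..block_index with dropout
    disabled; the (positions, channels) block output is flattened
    channel-major — element (c, p) of the map lands at flat index
    ``c * positions + p``.  Rows are tagged source="real" and carry the
    record's label.
    """
    if not 1 <= block_index <= 5:
        raise ValueError("block_index must lie in 1..5")
    X, y = encode_batch(records)
    maps = forward_logits(model, X, train=False, upto_block=block_index).data
    n, positions, channels = maps.shape
    flat = maps.transpose(0, 2, 1).reshape(n, channels * positions)
    return FeatureBatch(flat, y.astype(int), np.array(["real"] * n),
                        (channels, positions))


# ---------------------------------------------------------------------------
# GAN configuration and networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GanConfig:
    noise_dim: int = 128
    penalty_coefficient: float = 10.0
    critic_steps: int = 5
    learning_rate: float = 1e-4
    adam_betas: tuple[float, float] = (0.0, 0.9)
    total_epochs: int = 2000
    checkpoint_interval: int = 200
    batch_size: int = 64
    hidden_sizes: tuple[int, int] = (128, 128)
    seed: int = 0

    def __post_init__(self):
        if self.total_epochs < self.checkpoint_interval:
            raise ValueError("total_epochs must be >= checkpoint_interval")
        if self.total_epochs % self.checkpoint_interval != 0:
            raise ValueError("checkpoint_interval must divide total_epochs")
        if self.penalty_coefficient <= 0 or self.learning_rate <= 0:
            raise ValueError("penalty coefficient and learning rate must be positive")


@dataclass
class GanCheckpoint:
    """Generator parameters at one training epoch."""

    epoch: int
    generator_params: dict[str, np.ndarray]
    hidden_sizes: tuple[int, int]
    noise_dim: int
    out_dim: int
    ctst_accuracy: float | None = None

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.generator_params)
        path.with_suffix(".json").write_text(json.dumps({
            "epoch": self.epoch, "hidden_sizes": list(self.hidden_sizes),
            "noise_dim": self.noise_dim, "out_dim": self.out_dim,
            "ctst_accuracy": self.ctst_accuracy}))

    @classmethod
    def load(cls, path: str | Path) -> "GanCheckpoint":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        return cls(epoch=meta["epoch"],
                   generator_params={k: data[k] for k in data.files},
                   hidden_sizes=tuple(meta["hidden_sizes"]),
                   noise_dim=meta["noise_dim"], out_dim=meta["out_dim"],
                   ctst_accuracy=meta["ctst_accuracy"])


def _init_mlp(sizes: tuple[int, ...], rng: np.random.Generator,
              prefix: str) -> dict[str, Tensor]:
    params = {}
    for i in range(len(sizes) - 1):
        params[f"{prefix}W{i}"] = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]),
                       size=(sizes[i], sizes[i + 1])), requires_grad=True)
        params[f"{prefix}b{i}"] = Tensor(np.zeros(sizes[i + 1]),
                                         requires_grad=True)
    return params


def _mlp_forward(x: Tensor, params: dict[str, Tensor], prefix: str,
                 n_layers: int) -> Tensor:
    h = x
    for i in range(n_layers):
        h = ad.add(ad.matmul(h, params[f"{prefix}W{i}"]),
                   params[f"{prefix}b{i}"])
        if i < n_layers - 1:
            h = ad.leaky_relu(h, _GAN_SLOPE)
    return h  # linear output


class CriticFn:
    """Callable critic D: (n, d) -> (n, 1), parameters exposed for training."""

    def __init__(self, d: int, hidden: tuple[int, int],
                 rng: np.random.Generator):
        self.params = _init_mlp((d, *hidden, 1), rng, "D.")

    def __call__(self, x: Tensor) -> Tensor:
        return _mlp_forward(x, self.params, "D.", 3)


class GeneratorFn:
    """Callable generator G: (n, noise_dim) -> (n, d)."""

    def __init__(self, noise_dim: int, hidden: tuple[int, int], d: int,
                 rng: np.random.Generator):
        self.noise_dim = noise_dim
        self.params = _init_mlp((noise_dim, *hidden, d), rng, "G.")

    def __call__(self, z: Tensor) -> Tensor:
        return _mlp_forward(z, self.params, "G.", 3)

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}


# ---------------------------------------------------------------------------
# gradient penalty
# ---------------------------------------------------------------------------

def _gradient_penalty_t(critic, real: np.ndarray, fake: np.ndarray,
                        lam: float, rng: np.random.Generator) -> Tensor:
    """Differentiable gradient-penalty term (a Tensor with graph)."""
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must share a shape")
    eps = rng.random((len(real), 1))
    x_hat = Tensor(eps * real + (1.0 - eps) * fake, requires_grad=True)
    d_hat = critic(x_hat)
    g_x, = ad.grad(ad.tsum(d_hat), [x_hat], create_graph=True)
    norm = ad.sqrt(ad.tsum(ad.mul(g_x, g_x), axis=1))
    return ad.mul(ad.tmean(ad.tpow(norm - 1.0, 2.0)), lam)


def gradient_penalty(critic, real_batch: np.ndarray, fake_batch: np.ndarray,
                     lam: float, seed: int = 0) -> float:
    """WGAN-GP penalty: lambda * E[(||grad_x D(x_hat)||_2 - 1)^2] over random
    interpolates x_hat = eps*x_real + (1-eps)*x_fake, eps ~ U(0,1) per row.

    ``critic`` is any callable mapping a Tensor (n, d) to scores (n, 1).
    Always non-negative.
    """
    rng = np.random.default_rng(seed)
    return _gradient_penalty_t(critic, np.asarray(real_batch, dtype=float),
                               np.asarray(fake_batch, dtype=float),
                               lam, rng).item()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_wgan_gp(real: FeatureBatch, config: GanConfig) -> list[GanCheckpoint]:
    """Train one WGAN-GP on single-class real features; emit periodic checkpoints.

    An epoch is a full shuffled pass over the real rows.  Each minibatch
    performs one critic update; after every ``critic_steps`` critic updates
    one generator update runs.  A :class:`GanCheckpoint` is captured every
    ``checkpoint_interval`` epochs.  Deterministic given ``config.seed``.
    """
    if len(np.unique(real.labels)) != 1:
        raise ValueError("WGAN-GP training is per class; mixed labels passed")
    if real.n < 2 * config.batch_size:
        raise ValueError(f"need >= {2 * config.batch_size} real rows, "
                         f"got {real.n}")
    d = real.d
    master = np.random.SeedSequence(config.seed)
    init_rng, loop_rng = (np.random.default_rng(s) for s in master.spawn(2))
    critic = CriticFn(d, config.hidden_sizes, init_rng)
    gen = GeneratorFn(config.noise_dim, config.hidden_sizes, d, init_rng)
    opt_d = ad.Adam(critic.params, lr=config.learning_rate,
                    betas=config.adam_betas)
    opt_g = ad.Adam(gen.params, lr=config.learning_rate,
                    betas=config.adam_betas)

    X = real.values
    lam = config.penalty_coefficient
    checkpoints: list[GanCheckpoint] = []
    since_gen = 0
    for epoch in range(1, config.total_epochs + 1):
        order = loop_rng.permutation(real.n)
        for i in range(0, real.n, config.batch_size):
            xb = X[order[i:i + config.batch_size]]
            z = loop_rng.standard_normal((len(xb), config.noise_dim))
            fake = gen(Tensor(z)).detach()  # critic step: generator constant
            d_real = ad.tmean(critic(Tensor(xb)))
            d_fake = ad.tmean(critic(fake))
            gp = _gradient_penalty_t(critic, xb, fake.data, lam, loop_rng)
            # critic minimizes -(E[D(real)] - E[D(fake)]) + gp
            loss_d = ad.add(ad.add(ad.mul(d_real, -1.0), d_fake), gp)
            grads = ad.grad(loss_d, list(critic.params.values()))
            opt_d.step({k: g.data for k, g in zip(critic.params, grads)})
            since_gen += 1
            if since_gen >= config.critic_steps:
                since_gen = 0
                z = loop_rng.standard_normal((config.batch_size,
                                              config.noise_dim))
                # generator minimizes -E[D(G(z))]
                loss_g = ad.mul(ad.tmean(critic(gen(Tensor(z)))), -1.0)
                grads = ad.grad(loss_g, list(gen.params.values()))
                opt_g.step({k: g.data for k, g in zip(gen.params, grads)})
        if epoch % config.checkpoint_interval == 0:
            checkpoints.append(GanCheckpoint(
                epoch=epoch, generator_params=gen.snapshot(),
                hidden_sizes=config.hidden_sizes,
                noise_dim=config.noise_dim, out_dim=d))
    return checkpoints


def generate_synthetic(checkpoint: GanCheckpoint, n: int, class_label: int,
                       layer_shape: tuple[int, int], seed: int) -> FeatureBatch:
    """Sample ``n`` synthetic feature vectors from a generator checkpoint."""
    if n < 1:
        raise ValueError("n must be >= 1")
    c, p = layer_shape
    if c * p != checkpoint.out_dim:
        raise ValueError(f"layer_shape {layer_shape} incompatible with "
                         f"generator output dim {checkpoint.out_dim}")
    params = {k: Tensor(v) for k, v in checkpoint.generator_params.items()}
    rng = np.random.default_rng(seed)
    z = Tensor(rng.standard_normal((n, checkpoint.noise_dim)))
    values = _mlp_forward(z, params, "G.", 3).data
    return FeatureBatch(values, np.full(n, class_label, dtype=int),
                        np.array(["synthetic"] * n), layer_shape)
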