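"""Stage-2 fine-tuning on real plus synthetic intermediate features.

Selected synthetic feature vectors are reshaped back into (channels,
positions) maps and injected into the network at the extraction layer (the
output of the frozen prefix).  Each fine-tuning epoch trains the unfrozen
suffix — conv blocks after the frozen prefix plus the fully connected head —
on a shuffled union of (a) real training records pushed through the frozen
blocks and (b) the reshaped synthetic maps labeled by their generating GAN's
class.  The frozen prefix (default: conv blocks 1-3, weights and biases) is
bit-identical before and after.  Early stopping mirrors stage 1: validation
AUC on real records only, best checkpoint returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .gan import FeatureBatch
from .metrics import roc_auc
from .network import (ModelState, TrainingConfig, TrainingHistory,
                      _sgd_epochs, forward_logits, predict_proba)
from .seqio import DatasetSplit, SequenceRecord, encode_batch, subset


@dataclass(frozen=True)
class FinetuneConfig(TrainingConfig):
    learning_rate: float = 1e-4  # Adam, the fine-tuning rate
    frozen_blocks: int = 3

    def __post_init__(self):
        super().__post_init__()
        if not 0 < self.frozen_blocks < 5:
            raise ValueError("frozen_blocks must lie in 1..4 "
                             "(freezing all five leaves nothing to tune)")


def reshape_to_layer(flat: FeatureBatch | np.ndarray,
                     layer_shape: tuple[int, int]) -> np.ndarray:
    """Reshape flat feature rows into (n, channels, positions) maps.

    Inverse of the channel-major flattening used at extraction: map element
    (c, p) is flat element ``c * positions + p``; flatten(reshape(x)) == x.
    """
    values = flat.values if isinstance(flat, FeatureBatch) else np.asarray(flat)
    c, p = layer_shape
    if values.shape[1] != c * p:
        raise ValueError(f"cannot reshape d={values.shape[1]} rows to "
                         f"layer shape {layer_shape} ({c}x{p}={c * p})")
    return values.reshape(len(values), c, p)


def finetune_stage2(model: ModelState, records: list[SequenceRecord],
                    split: DatasetSplit, synth_pos: FeatureBatch,
                    synth_neg: FeatureBatch, config: FinetuneConfig
                    ) -> tuple[ModelState, TrainingHistory]:
    """Fine-tune the unfrozen suffix of a stage-1 model on real + synthetic maps.

    ``synth_pos`` / ``synth_neg`` must carry the layer shape of the frozen
    prefix's output (conv block ``config.frozen_blocks``).  Synthetic rows
    get labels 1 / 0 respectively and are mixed into the same shuffled
    batches as the real rows.  Validation and any later test evaluation see
    real records only.  The input model is not mutated; a new state is
    returned whose frozen-prefix parameters are byte-identical to it.
    """
    k = config.frozen_blocks
    expected = model.spec.block_output_shape(k)
    for name, fb in (("synth_pos", synth_pos), ("synth_neg", synth_neg)):
        if fb.n and fb.layer_shape != expected:
            raise ValueError(f"{name} layer_shape {fb.layer_shape} does not "
                             f"match block-{k} output {expected}")
        if fb.n and not np.all(fb.source == "synthetic"):
            raise ValueError(f"{name} contains non-synthetic rows")

    train_recs = subset(records, split.train_ids)
    val_recs = subset(records, split.val_ids)
    if not train_recs or not val_recs:
        raise ValueError("train and validation sets must be non-empty")
    X_tr, y_tr = encode_batch(train_recs)
    X_va, y_va = encode_batch(val_recs)
    if len(np.unique(y_va)) < 2:
        raise ValueError("validation set must contain both classes")

    state = model.copy()
    for i in range(1, k + 1):
        state.trainable[f"conv_{i}"] = False
    unfrozen = [n for n, t in state.trainable.items() if t]

    # real records pass through the frozen prefix once, dropout off
    # (dropout stays active only in the unfrozen blocks during training)
    prefix_maps = forward_logits(state, X_tr, train=False, upto_block=k).data
    # network layout is (n, positions, channels); synthetic maps arrive as
    # (n, channels, positions) and are transposed on injection
    pools = [(prefix_maps, y_tr)]
    if synth_pos.n:
        pools.append((reshape_to_layer(synth_pos, expected).transpose(0, 2, 1),
                      np.ones(synth_pos.n)))
    if synth_neg.n:
        pools.append((reshape_to_layer(synth_neg, expected).transpose(0, 2, 1),
                      np.zeros(synth_neg.n)))
    X_pool = np.concatenate([m for m, _ in pools])
    y_pool = np.concatenate([y for _, y in pools])

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    def batches(rng_):
        order = rng_.permutation(len(X_pool))
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            yield X_pool[idx], y_pool[idx]

    def val_auc(st):
        return roc_auc(y_va.astype(int), predict_proba(st, X_va))[0]

    history = _sgd_epochs(state, unfrozen, batches, val_auc, config, rng,
                          config.learning_rate, from_block=k + 1)
    history.train_pool_size = len(X_pool)
    return state, history
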