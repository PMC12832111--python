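import numpy as np
import pytest

import methylgan as mg
from methylgan.network import ConvBlockSpec, NetworkSpec


@pytest.fixture(scope="session")
def tiny_spec():
    """Five minimal conv blocks — fast enough for per-test training."""
    return NetworkSpec(
        conv_blocks=tuple(ConvBlockSpec(3, 4, 0.1) for _ in range(5)),
        leaky_slope=0.01, fc_widths=(8, 8), input_shape=(4, 41))


@pytest.fixture(scope="session")
def motif_dataset():
    """300 + 300 planted-motif records at the default strength."""
    return mg.generate_motif_dataset(300, 300, 41, mg.default_motif(0.8),
                                     seed=11)


@pytest.fixture(scope="session")
def trained_tiny(motif_dataset, tiny_spec):
    """A briefly trained tiny model plus its records and split."""
    split = mg.make_splits(motif_dataset, seed=12)
    cfg = mg.TrainingConfig(max_epochs=5, patience=5, seed=13)
    state, history = mg.train_stage1(motif_dataset, split, tiny_spec, cfg)
    return {"records": motif_dataset, "split": split, "state": state,
            "history": history}
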