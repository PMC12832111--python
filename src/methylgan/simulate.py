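"""Planted-motif simulator producing benchmark-shaped 6mA datasets.

Positives carry a position weight matrix (PWM) centered on the site; negatives
are background sequence.  Both classes have 'A' forced at the central
position, mirroring the real benchmark in which negatives are unmethylated
adenines — so the central base itself is uninformative and a classifier must
learn the flanking motif.  A ``strength`` dial mixes the PWM with background:
0 makes the classes identically distributed, 1 uses the PWM as-is.

This is a test fixture for the training pipeline, not a biological simulator:
it makes no attempt to match real 6mA k-mer statistics or known methylation
motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import ALPHABET, SequenceRecord

#: arbitrary fixed consensus word for the default motif (width 9, central 'A')
_DEFAULT_CONSENSUS = "GGTCACTGG"


@dataclass(frozen=True)
class MotifModel:
    """A centered PWM over a uniform-ish background.

    ``pwm`` is 4 x w (rows A, C, G, T); ``background`` is a length-4
    probability vector; ``strength`` in [0, 1] mixes the two column-wise.
    The central PWM column must put all its mass on 'A' (the site itself).
    """

    pwm: np.ndarray
    background: np.ndarray
    strength: float

    def __post_init__(self):
        pwm = np.asarray(self.pwm, dtype=np.float64)
        bg = np.asarray(self.background, dtype=np.float64)
        object.__setattr__(self, "pwm", pwm)
        object.__setattr__(self, "background", bg)
        if pwm.shape[0] != 4 or bg.shape != (4,):
            raise ValueError("pwm must be 4 x w and background length 4")
        if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("pwm columns must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        center = pwm.shape[1] // 2
        if not np.isclose(pwm[0, center], 1.0, atol=1e-9):
            raise ValueError("central pwm column must assign probability 1 to 'A'")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")

    @property
    def width(self) -> int:
        return self.pwm.shape[1]


def default_motif(strength: float = 0.8, consensus_mass: float = 0.9) -> MotifModel:
    """Width-9 consensus-like motif: ``consensus_mass`` on the consensus base
    per flanking position, the rest spread evenly; uniform background."""
    w = len(_DEFAULT_CONSENSUS)
    pwm = np.full((4, w), (1.0 - consensus_mass) / 3.0)
    for j, base in enumerate(_DEFAULT_CONSENSUS):
        pwm[ALPHABET.index(base), j] = consensus_mass
    pwm[:, w // 2] = [1.0, 0.0, 0.0, 0.0]  # the site itself is always 'A'
    return MotifModel(pwm=pwm, background=np.full(4, 0.25), strength=strength)


def _sample_class(n: int, l: int, probs: np.ndarray, prefix: str,
                  label: int, rng: np.random.Generator) -> list[SequenceRecord]:
    # probs: 4 x l per-position base probabilities, center already forced to A
    records = []
    cum = probs.T.cumsum(axis=1)  # l x 4
    width = len(str(max(n - 1, 1)))
    for i in range(n):
        u = rng.random(l)
        idx = (u[:, None] < cum).argmax(axis=1)
        seq = "".join(ALPHABET[j] for j in idx)
        records.append(SequenceRecord(f"{prefix}_{i:0{width}d}", seq, label))
    return records


def generate_motif_dataset(n_pos: int, n_neg: int, l: int,
                           motif: MotifModel, seed: int) -> list[SequenceRecord]:
    """Draw ``n_pos`` motif-bearing positives and ``n_neg`` background negatives.

    The motif occupies the central ``w`` positions of each positive, its
    columns mixed with background as ``strength * pwm + (1-strength) * bg``;
    everything else is background.  Both classes get 'A' at index ``l // 2``.
    Deterministic given ``seed``.
    """
    if l % 2 == 0:
        raise ValueError("sequence length l must be odd (site-centered window)")
    if motif.width > l:
        raise ValueError(f"motif width {motif.width} exceeds sequence length {l}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    center = l // 2
    start = center - motif.width // 2

    bg_probs = np.tile(motif.background[:, None], (1, l))
    pos_probs = bg_probs.copy()
    mixed = motif.strength * motif.pwm + (1 - motif.strength) * motif.background[:, None]
    pos_probs[:, start:start + motif.width] = mixed
    onehot_a = np.array([1.0, 0.0, 0.0, 0.0])
    pos_probs[:, center] = onehot_a
    neg_probs = bg_probs.copy()
    neg_probs[:, center] = onehot_a

    pos = _sample_class(n_pos, l, pos_probs, "pos", 1, rng)
    neg = _sample_class(n_neg, l, neg_probs, "neg", 0, rng)
    return pos + neg


def log_odds_scores(records: list[SequenceRecord], motif: MotifModel,
                    l: int | None = None) -> np.ndarray:
    """PWM-vs-background log-odds score of each record's central window.

    A simple independent scorer used to sanity-check separability of the
    generated data (higher score = more motif-like).  A small pseudo-weight
    keeps log(0) out of degenerate PWMs.
    """
    eps = 1e-6
    pwm = (motif.pwm + eps) / (motif.pwm + eps).sum(axis=0)
    bg = (motif.background + eps) / (motif.background + eps).sum()
    llr = np.log(pwm / bg[:, None])
    scores = np.empty(len(records))
    for k, r in enumerate(records):
        seq = r.sequence
        center = len(seq) // 2
        start = center - motif.width // 2
        window = seq[start:start + motif.width]
        scores[k] = sum(llr[ALPHABET.index(b), j] for j, b in enumerate(window))
    return scores
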