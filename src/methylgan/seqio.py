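"""Reading, validating, one-hot encoding and splitting labeled 6mA datasets.

The benchmark convention is a fixed-length site-centered window (41 bp): the
candidate adenine sits at 0-based index ``l // 2`` of every record, labeled 1
if it carries N6-methyladenine and 0 otherwise.  Two on-disk dialects are
accepted — standard FASTA and bare one-sequence-per-line text — auto-detected
from the first non-blank character.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

#: fixed row order of the one-hot encoding
ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class ValidationError(ValueError):
    """A record violates the dataset conventions."""


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled site-centered DNA sequence."""

    identifier: str
    sequence: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValidationError(f"{self.identifier}: label must be 0 or 1")


def validate_records(records: list[SequenceRecord], *,
                     require_central_a: bool = True) -> None:
    """Check alphabet, length consistency and the central-adenine convention.

    Alphabet and length violations raise :class:`ValidationError`.  Records
    whose central base is not 'A' are flagged with a warning (the benchmark
    convention, not a hard property of arbitrary data); pass
    ``require_central_a=False`` to silence the check.
    """
    if not records:
        raise ValidationError("empty dataset")
    length = len(records[0].sequence)
    offenders = []
    for r in records:
        bad = set(r.sequence) - set(ALPHABET)
        if bad:
            raise ValidationError(
                f"record {r.identifier!r}: invalid characters {sorted(bad)} "
                f"(alphabet is strictly A/C/G/T; ambiguity codes rejected)")
        if len(r.sequence) != length:
            raise ValidationError(
                f"record {r.identifier!r}: length {len(r.sequence)} != {length}")
        if require_central_a and r.sequence[length // 2] != "A":
            offenders.append(r.identifier)
    if offenders:
        log.warning("%d record(s) lack 'A' at the central position "
                    "(first: %s) — not benchmark-convention data",
                    len(offenders), offenders[0])


def _read_one_file(path: Path, label: int) -> list[SequenceRecord]:
    text = path.read_text()
    first = next((c for c in text if not c.isspace()), "")
    records: list[SequenceRecord] = []
    if first == ">":
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(SequenceRecord(rec.id, str(rec.seq).upper(), label))
    else:
        for i, line in enumerate(text.splitlines()):
            line = line.strip()
            if not line:
                continue
            records.append(SequenceRecord(f"{path.stem}_{i}", line.upper(), label))
    return records


def read_benchmark(positive_path: str | Path, negative_path: str | Path, *,
                   require_central_a: bool = True) -> list[SequenceRecord]:
    """Read a positive and a negative file into one labeled record list.

    Each file may be FASTA ('>' headers, parsed with Biopython) or plain
    one-sequence-per-line text.  Sequences are uppercased; validation is run
    on the combined list.
    """
    pos = _read_one_file(Path(positive_path), 1)
    neg = _read_one_file(Path(negative_path), 0)
    log.info("read %d positive records from %s", len(pos), positive_path)
    log.info("read %d negative records from %s", len(neg), negative_path)
    records = pos + neg
    validate_records(records, require_central_a=require_central_a)
    return records


# ---------------------------------------------------------------------------
# one-hot encoding
# ---------------------------------------------------------------------------

def one_hot_encode(sequence: str | SequenceRecord) -> np.ndarray:
    """Encode a sequence as a 4 x l binary matrix, rows ordered A, C, G, T.

    Each base maps to an indicator column: A -> (1,0,0,0), C -> (0,1,0,0),
    G -> (0,0,1,0), T -> (0,0,0,1).
    """
    seq = sequence.sequence if isinstance(sequence, SequenceRecord) else sequence
    try:
        idx = [_BASE_INDEX[b] for b in seq]
    except KeyError as e:
        raise ValidationError(f"invalid character {e.args[0]!r} in sequence")
    mat = np.zeros((4, len(seq)), dtype=np.int8)
    mat[idx, np.arange(len(seq))] = 1
    return mat


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` (argmax per column)."""
    return "".join(ALPHABET[i] for i in np.asarray(matrix).argmax(axis=0))


def encode_batch(records: list[SequenceRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Encode records into network layout.

    Returns ``X`` of shape (n, l, 4) — the per-record 4 x l one-hot matrices
    transposed to length-major, which is the layout the convolutional network
    consumes — and the label vector ``y`` of shape (n,).
    """
    X = np.stack([one_hot_encode(r).T for r in records]).astype(np.float64)
    y = np.array([r.label for r in records], dtype=np.float64)
    return X, y


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train / validation / test identifier sets."""

    train_ids: frozenset[str]
    val_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int

    def partition_of(self, identifier: str) -> str:
        if identifier in self.train_ids:
            return "train"
        if identifier in self.val_ids:
            return "val"
        if identifier in self.test_ids:
            return "test"
        raise KeyError(identifier)


def make_splits(records: list[SequenceRecord], seed: int) -> DatasetSplit:
    """Stratified 9:1 train/test split, then 1/9 of the train pool to validation.

    Within each class: floor(n/10) records go to test, floor(remaining/9) to
    validation, the rest to train.  Deterministic given ``seed``.
    """
    by_class: dict[int, list[str]] = {0: [], 1: []}
    for r in records:
        by_class[r.label].append(r.identifier)
    for lab, ids in by_class.items():
        if len(ids) < 10:
            raise ValidationError(
                f"class {lab} has {len(ids)} records; need >= 10 per class "
                "for a 9:1 split")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for lab in (0, 1):
        ids = np.array(sorted(by_class[lab]))
        rng.shuffle(ids)
        n_test = len(ids) // 10
        pool = ids[n_test:]
        n_val = len(pool) // 9
        test.extend(ids[:n_test])
        val.extend(pool[:n_val])
        train.extend(pool[n_val:])
    return DatasetSplit(frozenset(train), frozenset(val), frozenset(test), seed)


def subset(records: list[SequenceRecord], ids: frozenset[str]) -> list[SequenceRecord]:
    """Records whose identifier is in ``ids``, in original order."""
    return [r for r in records if r.identifier in ids]


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_linetext(records: list[SequenceRecord], path: str | Path) -> None:
    Path(path).write_text("".join(r.sequence + "\n" for r in records))


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.identifier}\n{r.sequence}\n")


def write_split_manifest(split: DatasetSplit, sequence_file: str,
                         path: str | Path) -> None:
    """3-column TSV: id, sequence_file, partition."""
    with open(path, "w") as fh:
        fh.write("id\tsequence_file\tpartition\n")
        for name, ids in (("train", split.train_ids), ("val", split.val_ids),
                          ("test", split.test_ids)):
            for i in sorted(ids):
                fh.write(f"{i}\t{sequence_file}\t{name}\n")
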