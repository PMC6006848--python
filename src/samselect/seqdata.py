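"""Core DNA sequence types, FASTA I/O and encoding conventions.

All coordinates are 0-based, half-open ``[start, end)`` internally; anything
printed for humans is converted to 1-based inclusive at the boundary.
Only the alphabet ``{A, C, G, T}`` is processed; the forward strand only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
#: 2-bit code per base, A=00, C=01, G=10, T=11.
BASE_CODE = {b: i for i, b in enumerate(ALPHABET)}
_CODE_BASE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

# byte value -> 2-bit code lookup, 255 marks a non-ACGT byte
_BYTE_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in BASE_CODE.items():
    _BYTE_CODE[ord(_b)] = _c
    _BYTE_CODE[ord(_b.lower())] = _c


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T}."""


class FastaError(ValueError):
    """Malformed FASTA input."""


def seq_to_codes(seq: str) -> np.ndarray:
    """Map a DNA string to its uint8 2-bit codes (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _BYTE_CODE[raw]
    if codes.size and codes.max() == 255:
        bad = chr(int(raw[codes == 255][0]))
        raise AlphabetError(f"character {bad!r} outside alphabet {ALPHABET}")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    """Inverse of :func:`seq_to_codes`."""
    return _CODE_BASE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


@dataclass(frozen=True)
class MotifSpec:
    """Parameters (l, d, q) of a quorum planted motif: length, maximum
    mismatches between motif and instance, and the quorum fraction."""

    l: int
    d: int
    q: float

    def __post_init__(self) -> None:
        if not 0 <= self.d < self.l:
            raise ValueError(f"require 0 <= d < l, got l={self.l}, d={self.d}")
        if not 0 < self.q <= 1:
            raise ValueError(f"require 0 < q <= 1, got q={self.q}")

    def quorum(self, t: int) -> int:
        """Minimum number of sequences an (l, d) motif must span: ceil(q*t)."""
        return int(-(-self.q * t // 1))


@dataclass
class Dataset:
    """An ordered multi-FASTA DNA dataset D = {s_1, ..., s_t}.

    ``n`` is the nominal (maximum) sequence length; ragged inputs are
    accepted and every per-sequence loop uses the actual length.
    """

    sequences: list[tuple[str, str]]
    _codes: list[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FastaError("no sequences")
        seen: set[str] = set()
        norm = []
        for sid, seq in self.sequences:
            if sid in seen:
                raise ValueError(f"duplicate sequence id {sid!r}")
            seen.add(sid)
            norm.append((sid, seq.upper()))
        self.sequences = norm
        # validates the alphabet eagerly and caches the 2-bit encoding
        self._codes = [seq_to_codes(seq) for _, seq in self.sequences]

    @property
    def t(self) -> int:
        return len(self.sequences)

    @property
    def n(self) -> int:
        return max(len(s) for _, s in self.sequences)

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.sequences]

    def codes(self, i: int) -> np.ndarray:
        """2-bit encoding of sequence ``i`` (cached)."""
        return self._codes[i]

    def __len__(self) -> int:
        return self.t

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.sequences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.sequences == other.sequences

    def subset(self, ids: Sequence[str]) -> "Dataset":
        """New Dataset restricted to ``ids``, in the given order."""
        by_id = dict(self.sequences)
        return Dataset([(sid, by_id[sid]) for sid in ids])


def read_fasta(
    path: str | Path,
    *,
    replace_n: bool = False,
    seed: int | None = None,
) -> Dataset:
    """Read a multi-FASTA file into a :class:`Dataset`.

    Sequences are upper-cased.  Non-ACGT characters are rejected with
    :class:`AlphabetError` unless ``replace_n`` is set, in which case any
    IUPAC ambiguity code (N, R, Y, ...) is replaced by a uniformly random
    base drawn under ``seed``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"no sequences in {path}")
    rng = np.random.default_rng(seed) if replace_n else None
    sequences = []
    for rec in records:
        seq = str(rec.seq).upper()
        if replace_n:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            bad = _BYTE_CODE[arr] == 255
            if bad.any():
                arr[bad] = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)[
                    rng.integers(0, 4, int(bad.sum()))
                ]
                seq = arr.tobytes().decode()
        sequences.append((rec.id, seq))
    return Dataset(sequences)


def write_fasta(dataset: Dataset, path: str | Path, *, width: int = 70) -> None:
    """Write a :class:`Dataset` as multi-FASTA (wrapped at ``width``)."""
    records = (
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in dataset
    )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def stn(y: str) -> int:
    """Integer encoding of a DNA string: reverse ``y``, then map bases to the
    2-bit codes A=00, C=01, G=10, T=11 and read the concatenation as a binary
    number.  Bijective between length-L strings and ``[0, 4**L)``.

    Reversing first makes the code of position j contribute ``4**j``, so a
    common *suffix* of two strings fixes the low-order bits — convenient when
    counts are filled in by backward (right-to-left) search.
    """
    if len(y) > 31:
        raise ValueError("stn supports strings up to length 31")
    codes = seq_to_codes(y)
    # reversed string: first char of the reversal is the most significant
    # digit, i.e. y[j] carries weight 4**j
    return int(codes @ (4 ** np.arange(len(y), dtype=np.uint64)))


def stn_inverse(value: int, length: int) -> str:
    """Inverse of :func:`stn` for strings of known ``length``."""
    if not 0 <= value < 4**length:
        raise ValueError("value out of range for given length")
    digits = (value >> (2 * np.arange(length))) & 3
    return codes_to_seq(digits)


def hamming(x: str, y: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} != {len(y)}")
    return sum(a != b for a, b in zip(x, y))


def neighbors(x: str, k: int) -> set[str]:
    """The Hamming ball B_k(x): every string of length |x| within distance k.

    Size is sum_{i<=k} C(|x|, i) * 3**i.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    k = min(k, len(x))
    out = {x}
    chars = list(x)
    for i in range(1, k + 1):
        for positions in itertools.combinations(range(len(x)), i):
            alts = [[b for b in ALPHABET if b != x[p]] for p in positions]
            for repl in itertools.product(*alts):
                y = chars.copy()
                for p, b in zip(positions, repl):
                    y[p] = b
                out.add("".join(y))
    return out


def neighbor_deltas(w: int, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Digit-level edit list generating B_k for 2-bit packed w-mers.

    Returns one ``(positions, deltas)`` pair per neighbor of the identity
    (identity itself excluded): replacing digit ``c`` at position ``p`` by
    ``(c + delta) % 4`` with delta in {1,2,3} enumerates exactly the strings
    at each Hamming distance 1..k, without duplicates.
    """
    out = []
    for i in range(1, min(k, w) + 1):
        for positions in itertools.combinations(range(w), i):
            for deltas in itertools.product((1, 2, 3), repeat=i):
                out.append(
                    (np.array(positions, dtype=np.int64),
                     np.array(deltas, dtype=np.int64))
                )
    return out


def window_codes(codes: np.ndarray, w: int) -> np.ndarray:
    """stn codes of every w-window of an encoded sequence, as int64.

    Entry j is ``stn`` of the window starting at j (weight ``4**i`` for the
    i-th character of the window).
    """
    codes = np.asarray(codes, dtype=np.int64)
    if len(codes) < w:
        return np.empty(0, dtype=np.int64)
    weights = 4 ** np.arange(w, dtype=np.int64)
    out = np.convolve(codes, weights[::-1], mode="valid")
    return out.astype(np.int64)
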