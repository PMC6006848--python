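"""Exact w-mer counting over a DNA dataset and mismatch-tolerant counts.

Two routes produce the same dense count table ``T`` of size ``4**w``:

* the reference route — depth-first search of the complete quadtree of
  strings of length <= w, carrying an FM-index rank interval down so each
  backward extension is O(1), pruning subtrees whose interval is empty;
* a direct vectorised tally of window codes (used by the pipeline), which
  is bit-identical and much faster in NumPy.

``count_k(x)``, the number of w-length windows of the dataset within
Hamming distance k of x, is the sum of ``T[stn(y)]`` over the Hamming ball
``B_k(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqdata import Dataset, neighbor_deltas, neighbors, seq_to_codes, stn, window_codes

MAX_W = 15  # 4**15 table entries; larger tables are refused


@dataclass(frozen=True)
class WordCountConfig:
    """Window length ``w`` and mismatch allowance ``k`` for frequency
    scanning (defaults w=12, k=1)."""

    w: int = 12
    k: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.k < self.w:
            raise ValueError(f"require 1 <= k < w, got w={self.w}, k={self.k}")
        if self.w > MAX_W:
            raise ValueError(f"w={self.w} exceeds maximum {MAX_W}")


def _suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling with numpy lexsort."""
    n = len(text)
    rank = np.asarray(text, dtype=np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[:-k] = rank[k:]
        order = np.lexsort((key2, rank))
        r2, k2 = rank[order], key2[order]
        changed = np.empty(n, dtype=bool)
        changed[0] = True
        changed[1:] = (r2[1:] != r2[:-1]) | (k2[1:] != k2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


class BackwardIndex:
    """FM-index over the dataset text supporting backward search.

    Sequences are joined by a sentinel (code 0, lexicographically smallest,
    outside the DNA alphabet) so no match spans two sequences.  For any
    ACGT string ``y``, the rank interval ``[L_y, R_y)`` of suffixes prefixed
    by ``y`` has width equal to the number of occurrences of ``y`` in the
    original sequences.
    """

    def __init__(self, dataset: Dataset):
        parts = []
        for i in range(dataset.t):
            parts.append(dataset.codes(i).astype(np.int64) + 1)  # A..T -> 1..4
            parts.append(np.zeros(1, dtype=np.int64))  # sentinel
        text = np.concatenate(parts)
        self.size = len(text)
        sa = _suffix_array(text)
        bwt = text[(sa - 1) % self.size]
        counts = np.bincount(text, minlength=5)
        # C[c]: number of text symbols strictly smaller than c
        self._C = np.concatenate(([0], np.cumsum(counts)))[:5]
        # occ[c, i]: occurrences of c in bwt[:i]
        one_hot = bwt[None, :] == np.arange(5)[:, None]
        self._occ = np.zeros((5, self.size + 1), dtype=np.int64)
        np.cumsum(one_hot, axis=1, out=self._occ[:, 1:])
        self.sa = sa

    def full_interval(self) -> tuple[int, int]:
        """Interval of the empty string: all suffixes."""
        return 0, self.size

    def extend(self, lo: int, hi: int, code: int) -> tuple[int, int]:
        """Backward-extend the interval of φ' to φ = b·φ' for base code
        ``code`` (0..3 for A..T)."""
        c = code + 1
        return (
            int(self._C[c] + self._occ[c, lo]),
            int(self._C[c] + self._occ[c, hi]),
        )

    def count(self, y: str) -> int:
        """Occurrences of ``y`` across all sequences (backward traversal,
        right to left)."""
        lo, hi = self.full_interval()
        for code in seq_to_codes(y)[::-1]:
            lo, hi = self.extend(lo, hi, int(code))
            if lo >= hi:
                return 0
        return hi - lo


def build_index(dataset: Dataset) -> BackwardIndex:
    return BackwardIndex(dataset)


def count_exact(index: BackwardIndex, y: str) -> int:
    return index.count(y)


@dataclass
class CountTable:
    """Dense table of exact w-mer counts, indexed by the stn encoding."""

    w: int
    values: np.ndarray  # uint32, length 4**w

    def count(self, y: str) -> int:
        if len(y) != self.w:
            raise ValueError(f"expected a {self.w}-mer, got length {len(y)}")
        return int(self.values[stn(y)])


def build_count_table(index: BackwardIndex, w: int) -> CountTable:
    """Reference construction: DFS of the depth-w quadtree of strings built
    by prepending characters, carrying the FM-index interval down; a node
    with an empty interval is pruned, a surviving leaf y writes
    ``T[stn(y)] = count(y)``.

    Because characters are prepended, every node's string is a common
    suffix of its descendants and its stn code is built incrementally:
    ``stn(b·φ') = code(b) + 4*stn(φ')``.
    """
    if not 1 <= w <= MAX_W:
        raise ValueError(f"require 1 <= w <= {MAX_W}, got {w}")
    values = np.zeros(4**w, dtype=np.uint32)
    lo0, hi0 = index.full_interval()
    # stack of (lo, hi, depth, stn-so-far); children pushed T..A so that
    # A is explored first (ascending encoding order)
    stack: list[tuple[int, int, int, int]] = [(lo0, hi0, 0, 0)]
    while stack:
        lo, hi, depth, acc = stack.pop()
        if depth == w:
            values[acc] = hi - lo
            continue
        for code in (3, 2, 1, 0):
            clo, chi = index.extend(lo, hi, code)
            if chi > clo:  # prune empty subtrees
                stack.append((clo, chi, depth + 1, acc * 4 + code))
    return CountTable(w, values)


def tally_count_table(dataset: Dataset, w: int) -> CountTable:
    """Fast path: direct tally of the stn codes of every w-window.

    Bit-identical to :func:`build_count_table` on the same dataset.
    """
    if not 1 <= w <= MAX_W:
        raise ValueError(f"require 1 <= w <= {MAX_W}, got {w}")
    chunks = [window_codes(dataset.codes(i), w) for i in range(dataset.t)]
    codes = np.concatenate(chunks) if chunks else np.empty(0, np.int64)
    if codes.size and codes.size >= 2**32:
        raise OverflowError("window count exceeds 32-bit table entries")
    values = np.bincount(codes, minlength=4**w).astype(np.uint32)
    return CountTable(w, values)


def count_with_mismatches(table: CountTable, x: str, k: int) -> int:
    """count_k(x): number of w-windows of the dataset within Hamming
    distance k of x, via neighborhood aggregation over B_k(x)."""
    if len(x) != table.w:
        raise ValueError(f"expected a {table.w}-mer, got length {len(x)}")
    if not 0 <= k < len(x):
        raise ValueError(f"require 0 <= k < |x|, got k={k}")
    return int(sum(int(table.values[stn(y)]) for y in neighbors(x, k)))


def count_all_windows(
    dataset: Dataset, table: CountTable, k: int
) -> list[np.ndarray]:
    """count_k of every w-window of every sequence.

    Returns one int64 array per sequence; entry j is count_k of the window
    starting at (0-based) position j.  Sequences shorter than w get an
    empty array.
    """
    w = table.w
    per_seq = [window_codes(dataset.codes(i), w) for i in range(dataset.t)]
    lengths = [len(c) for c in per_seq]
    codes = np.concatenate(per_seq) if per_seq else np.empty(0, np.int64)
    total = table.values[codes].astype(np.int64)
    for positions, deltas in neighbor_deltas(w, k):
        nb = codes.copy()
        for p, delta in zip(positions, deltas):
            shift = 2 * int(p)
            digit = (codes >> shift) & 3
            nb += (((digit + delta) % 4) - digit) << shift
        total += table.values[nb]
    out = []
    start = 0
    for m in lengths:
        out.append(total[start : start + m])
        start += m
    return out
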