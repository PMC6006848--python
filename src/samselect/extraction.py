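"""Stage 2: high-frequency substring obtainment.

High-count w-mers are selected per sequence, overlapping selections are
chained into substrings (set A), the total is capped by escalating the
threshold f, and long substrings are segmented at the maxima of their
attract tables into set A' so that each piece covers at most one motif
instance.

The inter-substring distance ``dis`` is the minimum Hamming distance over
all pairs of l-windows of the two substrings.  All pairwise distance work
is done on 2-bit-packed window codes with XOR + popcount, chunked to bound
memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqdata import Dataset, window_codes

_BITMASK = np.int64(0x5555555555555555)


@dataclass(frozen=True)
class HFSubstring:
    """A high-frequency substring with provenance: 0-based half-open
    coordinates into its source sequence."""

    seq_id: str
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.text):
            raise ValueError("coordinates inconsistent with text length")

    def __len__(self) -> int:
        return len(self.text)


@dataclass
class AttractTable:
    """Histogram over l-window start positions of a substring φ: entry i
    counts the other substrings whose nearest l-mer in φ starts at i."""

    owner: HFSubstring
    values: np.ndarray  # int64, length |φ| - l + 1


@dataclass
class ExtractionConfig:
    """Controls for stage 2.

    ``f_init`` defaults to round(N_r + N_m) from :mod:`samselect.theory`
    when left as None.  ``cap`` bounds |A| (escalating f by ~5% steps until
    it holds).  ``overlap_min`` is the minimum overlap (default ceil(w/2))
    for chaining selected windows; ``extend`` is the segmentation fringe.
    """

    f_init: int | None = None
    cap: int = 5000
    overlap_min: int | None = None
    extend: int = 3

    def resolved_overlap(self, w: int) -> int:
        ov = math.ceil(w / 2) if self.overlap_min is None else self.overlap_min
        if not 0 < ov <= w:
            raise ValueError(f"overlap_min must be in (0, w], got {ov}")
        return ov


# ---------------------------------------------------------------------------
# window-distance engine


def _pack(texts: list[str], l: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed codes of every l-window of every text, plus the offsets
    of each text's window block (length len(texts)+1)."""
    from .seqdata import seq_to_codes

    blocks = [window_codes(seq_to_codes(s), l) for s in texts]
    offsets = np.concatenate(([0], np.cumsum([len(b) for b in blocks])))
    codes = np.concatenate(blocks) if blocks else np.empty(0, np.int64)
    return codes, offsets


def _hamming_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances between two blocks of packed l-mers."""
    x = a[:, None] ^ b[None, :]
    return np.bitwise_count(((x | (x >> 1)) & _BITMASK).astype(np.uint64)).astype(
        np.uint8
    )


def window_sub_min(
    codes: np.ndarray, offsets: np.ndarray, *, chunk_rows: int | None = None
) -> np.ndarray:
    """Matrix M of shape (total windows, n_subs): M[i, s] is the minimum
    Hamming distance between window i and any window of substring s."""
    n_win = len(codes)
    n_sub = len(offsets) - 1
    if chunk_rows is None:  # ~64 MB of int64 intermediates per block
        chunk_rows = max(1, 8_000_000 // max(1, n_win))
    out = np.empty((n_win, n_sub), dtype=np.uint8)
    cols = offsets[:-1]
    for lo in range(0, n_win, chunk_rows):
        hi = min(lo + chunk_rows, n_win)
        block = _hamming_block(codes[lo:hi], codes)
        np.minimum.reduceat(block, cols, axis=1, out=out[lo:hi])
    return out


def dis_matrix_from_win(win_min: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Reduce the window-to-substring matrix to the substring-pair distance
    matrix (Eq-style min over both substrings' windows)."""
    return np.minimum.reduceat(win_min, offsets[:-1], axis=0)


def dis_matrix(texts: list[str], l: int) -> np.ndarray:
    """Symmetric matrix of ``dis`` over a list of substring texts."""
    codes, offsets = _pack(texts, l)
    return dis_matrix_from_win(window_sub_min(codes, offsets), offsets)


def dis(phi: str, phi2: str, l: int) -> int:
    """Minimum Hamming distance between any l-mer of phi and any l-mer of
    phi2; 0 iff they share an l-mer."""
    if len(phi) < l or len(phi2) < l:
        raise ValueError("both substrings must have length >= l")
    return int(dis_matrix([phi, phi2], l)[0, 1])


# ---------------------------------------------------------------------------
# selection and merging


def select_high_frequency(
    window_counts: list[np.ndarray], f: int
) -> list[np.ndarray]:
    """Per-sequence ascending window positions with count_k strictly
    greater than f."""
    return [np.flatnonzero(counts > f) for counts in window_counts]


def merge_overlaps(
    dataset: Dataset,
    selected: list[np.ndarray],
    w: int,
    overlap_min: int,
    l: int,
) -> list[HFSubstring]:
    """Chain selected w-mer windows that overlap by >= overlap_min
    characters into maximal substrings; keep those of length >= l.

    Two consecutive selected positions p < p' are chained when
    p' - p <= w - overlap_min; chains may combine more than two windows.
    Merging never crosses sequences.
    """
    out: list[HFSubstring] = []
    gap = w - overlap_min
    for i, positions in enumerate(selected):
        if len(positions) == 0:
            continue
        sid, seq = dataset.sequences[i]
        breaks = np.flatnonzero(np.diff(positions) > gap)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(positions) - 1]))
        for a, b in zip(starts, ends):
            lo = int(positions[a])
            hi = int(positions[b]) + w
            if hi - lo >= l:
                out.append(HFSubstring(sid, lo, hi, seq[lo:hi]))
    return out


@dataclass
class ExtractionResult:
    A: list[HFSubstring]
    f: int
    passes: int
    exhausted: bool = False  # selection went empty before the cap held


def extract_with_cap(
    dataset: Dataset,
    window_counts: list[np.ndarray],
    config: ExtractionConfig,
    w: int,
    l: int,
) -> ExtractionResult:
    """Select + merge at f = f_init, escalating f by max(1, ceil(0.05 f))
    while more than ``cap`` substrings survive."""
    if config.f_init is None:
        raise ValueError("f_init must be resolved before extraction")
    overlap_min = config.resolved_overlap(w)
    f = max(0, int(config.f_init))
    passes = 0
    while True:
        passes += 1
        selected = select_high_frequency(window_counts, f)
        A = merge_overlaps(dataset, selected, w, overlap_min, l)
        if len(A) <= config.cap:
            return ExtractionResult(A, f, passes)
        if all(len(p) == 0 for p in selected):  # pragma: no cover - defensive
            return ExtractionResult([], f, passes, exhausted=True)
        f += max(1, math.ceil(0.05 * f))


# ---------------------------------------------------------------------------
# attract tables and segmentation


def build_attract_tables(A: list[HFSubstring], l: int) -> list[AttractTable]:
    """Attract tables of every φ in A against A - {φ}, all computed from a
    single window-distance pass.

    For each φ' != φ, every argmin window position of φ (all ties) gets one
    increment: values[i] = |{φ' : i in minPos_φ(φ')}|.
    """
    codes, offsets = _pack([s.text for s in A], l)
    win_min = window_sub_min(codes, offsets)
    D = dis_matrix_from_win(win_min, offsets)
    tables = []
    for s, phi in enumerate(A):
        block = win_min[offsets[s] : offsets[s + 1]]  # (n_win_phi, n_sub)
        is_min = block == D[s][None, :]
        is_min[:, s] = False  # exclude φ itself
        tables.append(AttractTable(phi, is_min.sum(axis=1).astype(np.int64)))
    return tables


def build_attract_table(
    phi: HFSubstring, others: list[HFSubstring], l: int
) -> AttractTable:
    """Attract table of a single substring against ``others``."""
    if len(phi) < l:
        raise ValueError("substring shorter than l")
    values = np.zeros(len(phi) - l + 1, dtype=np.int64)
    if others:
        codes, offsets = _pack([phi.text] + [o.text for o in others], l)
        win_min = window_sub_min(codes, offsets)
        block = win_min[offsets[0] : offsets[1], 1:]
        mins = block.min(axis=0)
        values += (block == mins[None, :]).sum(axis=1)
    return AttractTable(phi, values)


def segment(
    phi: HFSubstring, table: AttractTable, l: int, extend: int = 3
) -> list[HFSubstring]:
    """Recursively cut φ at the attract-table maxima.

    The l-mer x at the (leftmost) maximum position i* is cut out and
    extended by up to ``extend`` characters on each side (clipped to φ);
    the remainders [0, i*) and [i*+l, |φ|) are segmented recursively using
    the original table restricted to window positions inside them.  Every
    returned piece has length in [l, l + 2*extend].
    """
    pieces: list[HFSubstring] = []
    values = table.values

    def rec(lo: int, hi: int) -> None:
        if hi - lo < l:
            return
        local = values[lo : hi - l + 1]
        i = lo + int(np.argmax(local))  # leftmost maximum
        cut_lo = max(0, i - extend)
        cut_hi = min(len(phi), i + l + extend)
        pieces.append(
            HFSubstring(
                phi.seq_id,
                phi.start + cut_lo,
                phi.start + cut_hi,
                phi.text[cut_lo:cut_hi],
            )
        )
        rec(lo, i)
        rec(i + l, hi)

    rec(0, len(phi))
    pieces.sort(key=lambda p: p.start)
    return pieces


def build_A_prime(
    A: list[HFSubstring], l: int, extend: int = 3
) -> list[HFSubstring]:
    """Segment every member of A at its attract-table maxima; the pieces
    (all of length >= l, provenance preserved) form A'."""
    if not A:
        raise ValueError("A must be non-empty")
    tables = build_attract_tables(A, l)
    out: list[HFSubstring] = []
    for phi, table in zip(A, tables):
        out.extend(segment(phi, table, l, extend))
    return out
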