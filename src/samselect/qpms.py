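"""A small exact quorum planted motif search (qPMS) solver.

Every (l, d) motif of a dataset is, by definition, a d-neighbor of each of
its instances, so enumerating the Hamming balls B_d(x) of every l-mer x of
every sequence provably covers all motifs.  The solver scores every
candidate code with the number of sequences containing an occurrence
within d (its support) and reports those meeting the quorum ceil(q*t).

Intended for sample-set scale (t up to ~200, l <= 13, d <= 3); larger
instances are refused with a cost estimate unless forced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqdata import (
    Dataset,
    neighbor_deltas,
    stn_inverse,
    window_codes,
)

_MAX_L = 13
_MAX_OPS = 2_000_000_000


@dataclass(frozen=True)
class MotifResult:
    motif: str
    support: int  # sequences with an occurrence within d
    total_min_dist: int  # sum of per-supporting-sequence minimum distances
    rank: int  # 1-based


class InstanceTooLarge(ValueError):
    """The (t, n, l, d) combination exceeds the solver's intended scale."""


def _cost_estimate(dataset: Dataset, l: int, d: int) -> int:
    n_windows = sum(max(0, len(s) - l + 1) for _, s in dataset)
    ball = sum(math.comb(l, i) * 3**i for i in range(d + 1))
    return n_windows * ball


def solve_qpms(
    dataset: Dataset, l: int, d: int, q: float, *, force: bool = False
) -> list[MotifResult]:
    """All l-mers occurring within d mismatches in at least ceil(q*t)
    sequences, ranked by support (desc), total minimum distance (asc),
    then lexicographically.
    """
    if not 0 <= d < l:
        raise ValueError("require 0 <= d < l")
    if not 0 < q <= 1:
        raise ValueError("require 0 < q <= 1")
    cost = _cost_estimate(dataset, l, d)
    if not force and (l > _MAX_L or cost > _MAX_OPS):
        raise InstanceTooLarge(
            f"instance too large for the exact solver: l={l}, d={d}, "
            f"~{cost:.2e} neighbor enumerations (limit {_MAX_OPS:.0e}); "
            "pass force=True to override"
        )
    space = 4**l
    deltas = neighbor_deltas(l, d)
    dist_of = np.concatenate(
        [np.zeros(1, np.uint8)] + [np.full(1, len(p), np.uint8) for p, _ in deltas]
    )
    support = np.zeros(space, dtype=np.int32)
    total_min = np.zeros(space, dtype=np.int64)
    scratch = np.full(space, 255, dtype=np.uint8)
    for i in range(dataset.t):
        codes = window_codes(dataset.codes(i), l)
        if codes.size == 0:
            continue
        blocks = [codes]
        dists = [np.zeros(len(codes), dtype=np.uint8)]
        for (positions, dl), dist in zip(deltas, dist_of[1:]):
            nb = codes.copy()
            for p, delta in zip(positions, dl):
                shift = 2 * int(p)
                digit = (codes >> shift) & 3
                nb += (((digit + delta) % 4) - digit) << shift
            blocks.append(nb)
            dists.append(np.full(len(codes), dist, dtype=np.uint8))
        cat = np.concatenate(blocks)
        catd = np.concatenate(dists)
        np.minimum.at(scratch, cat, catd)
        touched = np.unique(cat)
        hit = touched[scratch[touched] <= d]
        support[hit] += 1
        total_min[hit] += scratch[hit]
        scratch[touched] = 255  # reset for the next sequence
    quorum = math.ceil(q * dataset.t - 1e-12)
    codes = np.flatnonzero(support >= quorum)
    rows = sorted(
        (
            (-int(support[c]), int(total_min[c]), stn_inverse(int(c), l))
            for c in codes
        ),
    )
    return [
        MotifResult(motif, -neg_support, tmd, rank)
        for rank, (neg_support, tmd, motif) in enumerate(rows, start=1)
    ]


def rank_of(results: list[MotifResult], m: str) -> int | None:
    """1-based rank of motif m among the results, or None if absent."""
    for res in results:
        if res.motif == m:
            return res.rank
    return None


def estimate_q(dataset: Dataset, m: str, d: int) -> tuple[int, float]:
    """Scan the dataset with a known motif: Q = number of sequences with at
    least one occurrence of m within d mismatches, and q_hat = Q / t."""
    l = len(m)
    from .seqdata import seq_to_codes

    m_code = int(window_codes(seq_to_codes(m), l)[0])
    mask = np.int64(0x5555555555555555)
    Q = 0
    for i in range(dataset.t):
        codes = window_codes(dataset.codes(i), l)
        if codes.size == 0:
            continue
        x = codes ^ m_code
        dists = np.bitwise_count(((x | (x >> 1)) & mask).astype(np.uint64))
        if int(dists.min()) <= d:
            Q += 1
    return Q, Q / dataset.t
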