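"""Closed-form probabilities used across the pipeline.

* ``p_d(l, d)`` — probability that two uniform random l-mers are within
  Hamming distance d.
* ``p_span`` — probability that a random l-mer spans (occurs within d in)
  at least ceil(q*t) of t random n-length sequences.
* ``n_com`` — number of h-subsets of t - ceil(q*t) + h reference sequences
  a sample-pattern-driven solver must consider.
* ``expected_counts`` — expected mismatch-tolerant window counts for a
  background w-mer (N_r) and for a motif-instance w-mer (N_m); their sum
  seeds the high-frequency selection threshold f.
"""

from __future__ import annotations

import math

SIGMA = 4  # |Σ| for DNA


def _ceil_qt(q: float, t: int) -> int:
    """'At least qt sequences' rounded up."""
    return math.ceil(q * t - 1e-12)


def p_d(l: int, d: int) -> float:
    """P_d = sum_{i<=d} C(l,i) 3**i / 4**l."""
    if not 0 <= d <= l:
        raise ValueError(f"require 0 <= d <= l, got l={l}, d={d}")
    return sum(math.comb(l, i) * (SIGMA - 1) ** i for i in range(d + 1)) / SIGMA**l


def p_span(l: int, d: int, t: int, n: int, q: float) -> float:
    """Binomial tail: probability that an l-mer occurs (within d) in at
    least ceil(q*t) of t independent random n-length sequences."""
    pd = p_d(l, d)
    # per-sequence hit probability, treating the n-l+1 windows as independent
    p_hit = 1.0 - (1.0 - pd) ** (n - l + 1)
    lo = _ceil_qt(q, t)
    return float(
        sum(
            math.comb(t, i) * p_hit**i * (1.0 - p_hit) ** (t - i)
            for i in range(lo, t + 1)
        )
    )


def n_com(t: int, q: float, h: int) -> int:
    """N_com = C(t - ceil(q*t) + h, h)."""
    if h < 1:
        raise ValueError("h must be >= 1")
    return math.comb(t - _ceil_qt(q, t) + h, h)


def p_match(w: int, k: int) -> float:
    """Probability that two uniform random w-mers are within distance k
    (same form as P_d, at window scale)."""
    return p_d(w, k)


def expected_counts(
    w: int, k: int, l: int, d: int, q: float, t: int, n: int
) -> tuple[float, float]:
    """Expected count_k of a background window (N_r) and the expected
    extra contribution of motif instances to an instance window (N_m).

    N_r treats all t*(n-w+1) windows as uniform random w-mers.  N_m models
    the per-position disagreement between two instance-bearing windows as
    Bernoulli(beta) with beta = min(1, 2d/l): two instances of the same
    motif differ in at most 2d of the l motif positions.  The sum N_r + N_m
    seeds the selection threshold f; the downstream cap escalation makes
    the pipeline robust to the approximation.
    """
    nr = t * max(0, n - w + 1) * p_match(w, k)
    beta = min(1.0, 2.0 * d / l)
    nm = q * t * sum(
        math.comb(w, i) * beta**i * (1.0 - beta) ** (w - i) for i in range(k + 1)
    )
    return nr, nm
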