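"""Planted (l, d) motif dataset simulator with ground-truth sidecar.

Protocol: generate t i.i.d.-uniform n-length DNA sequences and a uniform
random l-mer motif m; choose ceil(q*t) distinct sequences; implant into
each one instance of m at a uniform position, overwriting the background.
An instance is built by choosing d distinct positions of m uniformly and
mutating each chosen position with probability g to a uniformly chosen
different base — so the per-instance mismatch count is Binomial(d, g) and
never exceeds d.  Lower g means higher conservation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .seqdata import Dataset, codes_to_seq, hamming


@dataclass(frozen=True)
class SimConfig:
    t: int
    n: int
    l: int
    d: int
    q: float
    g: float
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.d < self.l < self.n:
            raise ValueError("require 0 <= d < l < n")
        if not 0 < self.q <= 1:
            raise ValueError("require 0 < q <= 1")
        if not 0 <= self.g <= 1:
            raise ValueError("require 0 <= g <= 1")


@dataclass(frozen=True)
class Implant:
    seq_id: str
    position: int  # 0-based start of the instance
    instance: str
    mismatches: int


@dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset: the motif and every implant."""

    motif: str
    implants: list[Implant]

    @property
    def implanted_ids(self) -> set[str]:
        return {imp.seq_id for imp in self.implants}

    def to_json(self, path: str | Path) -> None:
        payload = {"motif": self.motif, "implants": [asdict(i) for i in self.implants]}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        return cls(payload["motif"], [Implant(**i) for i in payload["implants"]])


def generate(config: SimConfig) -> tuple[Dataset, PlantedTruth]:
    """Simulate a planted-motif dataset; deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    t, n, l, d, q, g = (
        config.t,
        config.n,
        config.l,
        config.d,
        config.q,
        config.g,
    )
    width = len(str(t - 1))
    background = rng.integers(0, 4, size=(t, n), dtype=np.int64)
    motif_codes = rng.integers(0, 4, size=l, dtype=np.int64)
    motif = codes_to_seq(motif_codes)
    n_implant = math.ceil(q * t - 1e-12)
    chosen = np.sort(rng.choice(t, size=n_implant, replace=False))
    implants: list[Implant] = []
    for idx in chosen:
        pos = int(rng.integers(0, n - l + 1))
        positions = rng.choice(l, size=d, replace=False)
        inst = motif_codes.copy()
        for p in positions:
            if rng.random() < g:
                inst[p] = (inst[p] + rng.integers(1, 4)) % 4
        background[idx, pos : pos + l] = inst
        instance = codes_to_seq(inst)
        implants.append(
            Implant(f"seq{idx:0{width}d}", pos, instance, hamming(instance, motif))
        )
    sequences = [
        (f"seq{i:0{width}d}", codes_to_seq(background[i])) for i in range(t)
    ]
    return Dataset(sequences), PlantedTruth(motif, implants)


def measured_q_prime(sequence_ids: list[str], truth: PlantedTruth) -> float:
    """Fraction of the given sequence ids that carry an implanted instance."""
    if not sequence_ids:
        return 0.0
    implanted = truth.implanted_ids
    return sum(sid in implanted for sid in sequence_ids) / len(sequence_ids)
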