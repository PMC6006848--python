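"""Stage 3: high-frequency substring grouping into sample sequence sets.

The segmented substrings A' are clustered with affinity propagation under
the similarity

    sim(φ, φ') = -dis(φ, φ')        if dis(φ, φ') <= 2d
               = -dis(φ, φ') * 10   otherwise,

clusters likely to describe the same motif are merged greedily, each
cluster is trimmed to the requested t' members nearest its center, and
three rules are enforced before a cluster may emit a sample set:

* Rule 1 — pairwise distances within the cluster are all <= 2d (any two
  instances of one motif are within 2d of each other);
* Rule 2 — every member is within 3d/2 of the cluster center (the center
  is expected to sit close to the motif itself);
* Rule 3 — the cluster weight w(c) = sum of pairwise distances does not
  exceed a_m = mu + sigma of the weights of randomly generated true
  motif-instance samples of the same size (otherwise members are removed
  in batches until it does, or the cluster is discarded).

The surviving clusters map to sample sequence sets D' (unique source
sequences), ranked by size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from . import theory
from .extraction import (
    ExtractionConfig,
    HFSubstring,
    build_A_prime,
    dis_matrix,
    extract_with_cap,
)
from .seqdata import Dataset, MotifSpec
from .wordcount import WordCountConfig, count_all_windows, tally_count_table

logger = logging.getLogger(__name__)


@dataclass
class GroupingConfig:
    """Controls for stage 3 (defaults follow the standard study settings:
    t'=100 requested samples, declared q'=0.95, 1000 calibration samples,
    Rule-3 removal batches of 10)."""

    t_prime_req: int = 100
    q_prime: float = 0.95
    ap_damping: float = 0.9
    ap_max_iter: int = 1000
    ap_convergence_iter: int = 100
    calib_samples: int = 1000
    removal_batch: int = 10
    min_cluster: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q_prime <= 1:
            raise ValueError("require 0 < q_prime <= 1")
        if self.removal_batch < 1:
            raise ValueError("removal_batch must be >= 1")


@dataclass
class Cluster:
    """A cluster of substrings with a designated exemplar (center).

    ``members`` are indices into the shared A' list / distance matrix.
    """

    members: list[int]
    center: int
    merged_from: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.center not in self.members:
            raise ValueError("center must be a member of the cluster")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SampleSet:
    """A selected sample sequence set D' with its declared q' and rank.

    ``member_substrings`` / ``center_substring`` carry the source cluster's
    actual substrings so the cluster can be audited without re-running the
    pipeline.
    """

    sequence_ids: list[str]
    t_prime: int
    q_prime: float
    rank: int
    source_cluster: Cluster
    member_substrings: list[HFSubstring] = field(default_factory=list)
    center_substring: HFSubstring | None = None


def similarity(phi: str, phi2: str, l: int, d: int) -> float:
    """Two-branch similarity: -dis if dis <= 2d, else -10*dis."""
    from .extraction import dis

    value = dis(phi, phi2, l)
    return float(-value if value <= 2 * d else -10 * value)


def similarity_matrix(D: np.ndarray, d: int) -> np.ndarray:
    S = -D.astype(np.float64)
    S[D > 2 * d] *= 10.0
    return S


def cluster_ap(
    D: np.ndarray, d: int, config: GroupingConfig
) -> list[Cluster]:
    """Affinity propagation on the precomputed distance matrix of A'.

    Preference is the median similarity (the standard default); damping and
    iteration limits come from the config.  If no exemplar emerges, the
    whole set collapses into a single medoid-centered cluster (logged).
    """
    n = len(D)
    if n < 2:
        return [Cluster(members=list(range(n)), center=0)] if n else []
    S = similarity_matrix(D, d)
    ap = AffinityPropagation(
        affinity="precomputed",
        damping=config.ap_damping,
        max_iter=config.ap_max_iter,
        convergence_iter=config.ap_convergence_iter,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = ap.fit_predict(S)
    centers = ap.cluster_centers_indices_
    if centers is None or len(centers) == 0:
        logger.warning("affinity propagation found no exemplars; "
                       "falling back to a single medoid cluster")
        medoid = int(np.argmin(D.sum(axis=1)))
        return [Cluster(members=list(range(n)), center=medoid)]
    clusters = []
    for k, center in enumerate(centers):
        members = [int(i) for i in np.flatnonzero(labels == k)]
        clusters.append(Cluster(members=members, center=int(center)))
    return clusters


def merge_clusters(
    clusters: list[Cluster], D: np.ndarray, l: int, d: int
) -> list[Cluster]:
    """Greedy merging: for a larger cluster c with center φ and a smaller
    c', merge when |{φ' in c' : dis(φ, φ') <= d}| > (P_d + 0.2) |c'|,
    i.e. significantly more members near φ than expected at random.
    Passes repeat until no merge fires."""
    pd = theory.p_d(l, d)
    clusters = [
        Cluster(list(c.members), c.center, list(c.merged_from)) for c in clusters
    ]
    changed = True
    while changed:
        changed = False
        clusters.sort(key=lambda c: -c.size)
        i = 0
        while i < len(clusters):
            ci = clusters[i]
            j = len(clusters) - 1
            while j > i:
                cj = clusters[j]
                near = sum(1 for m in cj.members if D[ci.center, m] <= d)
                if near > (pd + 0.2) * cj.size:
                    ci.members.extend(cj.members)
                    ci.merged_from.append(cj.center)
                    del clusters[j]
                    changed = True
                j -= 1
            i += 1
    return clusters


def trim_to_t_prime(
    cluster: Cluster, D: np.ndarray, t_prime_req: int
) -> Cluster:
    """Keep the t' members nearest the center (stable in insertion order)."""
    order = sorted(
        range(cluster.size),
        key=lambda i: (
            int(D[cluster.center, cluster.members[i]]),
            cluster.members[i] != cluster.center,  # center heads its tie group
        ),
    )
    kept = [cluster.members[i] for i in order[: max(1, t_prime_req)]]
    return Cluster(kept, cluster.center, list(cluster.merged_from))


def apply_rule1(cluster: Cluster, D: np.ndarray, d: int) -> Cluster:
    """Remove members until all pairwise distances are <= 2d.

    The member with the most violating pairs goes first (ties: larger
    distance to center, then later insertion order); the center itself is
    never removed.
    """
    members = list(cluster.members)
    bound = 2 * d
    while len(members) > 1:
        sub = D[np.ix_(members, members)]
        viol = (sub > bound).sum(axis=1)
        if viol.max() == 0:
            break
        cdist = D[cluster.center, members]
        worst = max(
            (i for i in range(len(members)) if members[i] != cluster.center),
            key=lambda i: (viol[i], cdist[i], i),
            default=None,
        )
        if worst is None or viol[worst] == 0:
            break
        del members[worst]
    return Cluster(members, cluster.center, list(cluster.merged_from))


def apply_rule2(cluster: Cluster, D: np.ndarray, d: int) -> Cluster:
    """Keep members within 3d/2 of the center (integer distances, so
    equivalent to <= floor(3d/2))."""
    bound = 1.5 * d
    members = [m for m in cluster.members if D[cluster.center, m] <= bound]
    return Cluster(members, cluster.center, list(cluster.merged_from))


def cluster_weight(cluster: Cluster, D: np.ndarray) -> int:
    """w(c): sum of dis over unordered member pairs."""
    sub = D[np.ix_(cluster.members, cluster.members)]
    return int(np.triu(sub, k=1).sum())


def calibrate_am(
    size: int,
    l: int,
    d: int,
    *,
    calib_samples: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Monte-Carlo threshold a_m = mu + sigma of sample weights.

    Each of ``calib_samples`` trials draws a fresh uniform l-mer motif and
    ``size`` instances (d distinct positions each, every chosen position
    mutated with probability 1/2 to a uniformly different base — the
    intermediate-conservation instance model), and scores the sample with
    the sum of Hamming distances over unordered instance pairs.
    """
    if size < 2:
        return 0.0, 0.0, 0.0
    rng = np.random.default_rng(seed)
    S = calib_samples
    motifs = rng.integers(0, 4, size=(S, 1, l), dtype=np.int8)
    inst = np.broadcast_to(motifs, (S, size, l)).copy()
    # d distinct positions per instance: first d columns of random argsorts
    positions = np.argsort(rng.random((S, size, l)), axis=2)[:, :, :d]
    mutate = rng.random((S, size, d)) < 0.5
    delta = rng.integers(1, 4, size=(S, size, d), dtype=np.int8)
    bump = np.where(mutate, delta, 0).astype(np.int8)
    cur = np.take_along_axis(inst, positions, axis=2)
    np.put_along_axis(inst, positions, (cur + bump) % 4, axis=2)
    weights = np.empty(S, dtype=np.int64)
    chunk = max(1, 40_000_000 // max(1, size * size * l))
    for lo in range(0, S, chunk):
        hi = min(S, lo + chunk)
        diff = inst[lo:hi, :, None, :] != inst[lo:hi, None, :, :]
        pair = diff.sum(axis=3, dtype=np.int64).sum(axis=(1, 2))
        weights[lo:hi] = pair // 2  # unordered pairs
    mu = float(weights.mean())
    sigma = float(weights.std())
    return mu + sigma, mu, sigma


@dataclass
class _AmCache:
    """Per-run cache of a_m calibrations keyed by cluster size."""

    l: int
    d: int
    calib_samples: int
    seed: int
    _store: dict[int, tuple[float, float, float]] = field(default_factory=dict)

    def get(self, size: int) -> float:
        if size not in self._store:
            self._store[size] = calibrate_am(
                size,
                self.l,
                self.d,
                calib_samples=self.calib_samples,
                seed=self.seed,
            )
        return self._store[size][0]


def apply_rule3(
    cluster: Cluster,
    D: np.ndarray,
    am_cache: _AmCache,
    config: GroupingConfig,
) -> Cluster | None:
    """Accept the cluster once w(c) <= a_m(|c|); otherwise iteratively
    remove the removal_batch members with the largest total distance to
    the rest (recalibrating a_m for the shrunken size).  Returns None if
    the cluster falls below min_cluster before acceptance."""
    members = list(cluster.members)
    while True:
        if len(members) < config.min_cluster:
            return None
        sub = D[np.ix_(members, members)]
        w = int(np.triu(sub, k=1).sum())
        if w <= am_cache.get(len(members)):
            return Cluster(members, cluster.center, list(cluster.merged_from))
        totals = sub.sum(axis=1, dtype=np.int64)
        order = sorted(
            (i for i in range(len(members)) if members[i] != cluster.center),
            key=lambda i: (-totals[i], -i),
        )
        drop = set(order[: config.removal_batch])
        if not drop:
            return None
        members = [m for i, m in enumerate(members) if i not in drop]


def emit_sample_sets(
    clusters: list[Cluster],
    A_prime: list[HFSubstring],
    D: np.ndarray,
    config: GroupingConfig,
) -> list[SampleSet]:
    """Map each surviving cluster to its sample sequence set: the unique
    source sequences of its members (a sequence contributing several
    members is represented by the one nearest the center).  Sets are
    ranked by size, ties broken by smaller mean member-to-center distance.
    """
    entries = []
    for cluster in clusters:
        best: dict[str, int] = {}
        for m in cluster.members:
            sid = A_prime[m].seq_id
            if sid not in best or D[cluster.center, m] < D[cluster.center, best[sid]]:
                best[sid] = m
        reps = sorted(best.values(), key=lambda m: (int(D[cluster.center, m]), m))
        ids = [A_prime[m].seq_id for m in reps]
        mean_dist = float(np.mean([D[cluster.center, m] for m in cluster.members]))
        entries.append((ids, mean_dist, cluster))
    entries.sort(key=lambda e: (-len(e[0]), e[1]))
    return [
        SampleSet(
            ids,
            len(ids),
            config.q_prime,
            rank,
            cluster,
            member_substrings=[A_prime[m] for m in cluster.members],
            center_substring=A_prime[cluster.center],
        )
        for rank, (ids, mean_dist, cluster) in enumerate(entries, start=1)
    ]


@dataclass
class SelectionReport:
    """Per-stage bookkeeping of a SamSelect run."""

    f_init: int
    f_final: int
    escalation_passes: int
    n_A: int
    n_A_prime: int
    n_clusters: int
    n_after_merge: int
    n_survivors: int


def select(
    dataset: Dataset,
    motif_spec: MotifSpec,
    wc_config: WordCountConfig | None = None,
    ex_config: ExtractionConfig | None = None,
    grp_config: GroupingConfig | None = None,
) -> tuple[list[SampleSet], SelectionReport]:
    """Run the full three-stage SamSelect pipeline.

    Stage 1 counts all w-windows with up to k mismatches; stage 2 extracts
    and segments high-frequency substrings; stage 3 clusters them and
    emits ranked sample sequence sets.
    """
    wc_config = wc_config or WordCountConfig()
    ex_config = ex_config or ExtractionConfig()
    grp_config = grp_config or GroupingConfig()
    l, d = motif_spec.l, motif_spec.d
    w, k = wc_config.w, wc_config.k

    table = tally_count_table(dataset, w)
    window_counts = count_all_windows(dataset, table, k)
    del table

    if ex_config.f_init is None:
        nr, nm = theory.expected_counts(
            w, k, l, d, motif_spec.q, dataset.t, dataset.n
        )
        ex_config = ExtractionConfig(
            f_init=int(round(nr + nm)),
            cap=ex_config.cap,
            overlap_min=ex_config.overlap_min,
            extend=ex_config.extend,
        )
    extraction = extract_with_cap(dataset, window_counts, ex_config, w, l)
    A = extraction.A
    logger.info("extraction: |A|=%d at f=%d", len(A), extraction.f)

    empty_report = lambda n_A, n_Ap: SelectionReport(
        ex_config.f_init, extraction.f, extraction.passes, n_A, n_Ap, 0, 0, 0
    )
    if not A:
        logger.warning("no high-frequency substrings survived extraction")
        return [], empty_report(0, 0)
    A_prime = build_A_prime(A, l, ex_config.extend)
    logger.info("segmentation: |A'|=%d", len(A_prime))
    if len(A_prime) < 2:
        return [], empty_report(len(A), len(A_prime))

    D = dis_matrix([s.text for s in A_prime], l)
    clusters = cluster_ap(D, d, grp_config)
    merged = merge_clusters(clusters, D, l, d)
    logger.info(
        "clustering: %d clusters, %d after merging", len(clusters), len(merged)
    )

    am_cache = _AmCache(l, d, grp_config.calib_samples, grp_config.seed)
    survivors = []
    for cluster in merged:
        c = trim_to_t_prime(cluster, D, grp_config.t_prime_req)
        c = apply_rule1(c, D, d)
        c = apply_rule2(c, D, d)
        c = apply_rule3(c, D, am_cache, grp_config)
        if c is not None:
            survivors.append(c)
    sample_sets = emit_sample_sets(survivors, A_prime, D, grp_config)
    report = SelectionReport(
        f_init=ex_config.f_init,
        f_final=extraction.f,
        escalation_passes=extraction.passes,
        n_A=len(A),
        n_A_prime=len(A_prime),
        n_clusters=len(clusters),
        n_after_merge=len(merged),
        n_survivors=len(survivors),
    )
    return sample_sets, report
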