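"""Alignment-free ANI estimation and greedy species-level genome clustering.

ANI between two sequences is estimated from the Jaccard index of their
canonical k-mer sets via the Mash distance formula

    d = -(1/k) * ln(2j / (1 + j)),    ani = max(0, 1 - d),

and alignment coverage is proxied by k-mer containment of the shorter
sequence.  Clustering is greedy and longest-first: each sequence joins the
first cluster whose representative it matches at >= ani_min ANI and
>= containment_min containment (defaults 0.95 / 0.80, the usual
species-level dereplication thresholds), else it founds a new cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._kmers import canonical_codes

DEFAULT_K = 16
DEFAULT_ANI_MIN = 0.95
DEFAULT_CONTAINMENT_MIN = 0.80


@dataclass(frozen=True)
class KmerSketch:
    """Canonical k-mer set of one sequence (full set, no MinHash subsampling).

    ``kmers`` holds sorted unique canonical k-mer codes in the 2-bit integer
    encoding of :mod:`prophagekit._kmers`.
    """

    sequence_id: str
    k: int
    kmers: np.ndarray
    seq_length: int

    @property
    def n_kmers(self) -> int:
        return int(self.kmers.size)


@dataclass(frozen=True)
class AniEstimate:
    """Pairwise ANI plus coverage of the shorter sequence.

    ``containment`` is the raw shared-k-mer fraction of the shorter
    sequence.  ``coverage`` corrects it for the k-mer survival expected at
    the estimated identity (a fully homologous but diverged sequence shares
    only ~ani^k of its k-mers), making it comparable to alignment coverage.
    """

    id_a: str
    id_b: str
    ani: float
    containment: float
    coverage: float


@dataclass(frozen=True)
class GenomeCluster:
    cluster_id: str
    representative_id: str
    member_ids: tuple[str, ...]


def sketch(sequence_id: str, sequence: str, k: int = DEFAULT_K) -> KmerSketch:
    """Build the canonical k-mer sketch of a sequence."""
    if k < 4:
        raise ValueError("k must be >= 4")
    if len(sequence) < k:
        raise ValueError(
            f"sequence {sequence_id!r} (length {len(sequence)}) shorter than k={k}"
        )
    codes = np.unique(canonical_codes(sequence, k))
    return KmerSketch(sequence_id, k, codes, len(sequence))


def estimate_ani(a: KmerSketch, b: KmerSketch) -> AniEstimate:
    """Mash-style ANI and shorter-sequence containment between two sketches."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    if a.n_kmers == 0 or b.n_kmers == 0:
        raise ValueError("cannot estimate ANI from an empty sketch")
    inter = np.intersect1d(a.kmers, b.kmers, assume_unique=True).size
    union = a.n_kmers + b.n_kmers - inter
    j = inter / union
    if j == 0:
        ani = 0.0
    else:
        d = -math.log(2 * j / (1 + j)) / a.k
        ani = min(1.0, max(0.0, 1.0 - d))
    shorter = a if a.seq_length <= b.seq_length else b
    containment = inter / shorter.n_kmers
    if ani > 0:
        coverage = min(1.0, containment / ani ** a.k)
    else:
        coverage = 0.0
    return AniEstimate(a.sequence_id, b.sequence_id, ani, containment, coverage)


def greedy_cluster(
    sketches: Sequence[KmerSketch],
    ani_min: float = DEFAULT_ANI_MIN,
    containment_min: float = DEFAULT_CONTAINMENT_MIN,
) -> list[GenomeCluster]:
    """Longest-first greedy clustering against cluster representatives.

    Sequences are visited by decreasing length (ties by id ascending); each
    joins the first existing cluster whose *representative* it matches at
    ani >= ani_min and divergence-corrected coverage >= containment_min,
    else founds a new cluster.  Deterministic by construction.
    """
    if not sketches:
        raise ValueError("need at least one sketch")
    ordered = sorted(sketches, key=lambda s: (-s.seq_length, s.sequence_id))
    reps: list[KmerSketch] = []
    members: list[list[str]] = []
    for sk in ordered:
        for i, rep in enumerate(reps):
            est = estimate_ani(sk, rep)
            if est.ani >= ani_min and est.coverage >= containment_min:
                members[i].append(sk.sequence_id)
                break
        else:
            reps.append(sk)
            members.append([sk.sequence_id])
    return [
        GenomeCluster(f"cluster_{i + 1}", rep.sequence_id, tuple(mem))
        for i, (rep, mem) in enumerate(zip(reps, members))
    ]


def cluster_summary(
    clusters: Sequence[GenomeCluster],
    prophage_ids: Iterable[str],
    phage_ids: Iterable[str],
) -> dict:
    """Partition prophages into co-clustered-with-known-phage, singleton, and
    prophage-only multi-member groups; report counts and percentages."""
    prophages = set(prophage_ids)
    phages = set(phage_ids)
    all_members = {m for c in clusters for m in c.member_ids}
    unlabeled = all_members - prophages - phages
    if unlabeled:
        raise ValueError(f"cluster members neither prophage nor phage: {sorted(unlabeled)}")

    co_clustered = singleton = prophage_only = 0
    co_clustered_clusters = 0
    for c in clusters:
        mem_pro = [m for m in c.member_ids if m in prophages]
        if not mem_pro:
            continue
        if any(m in phages for m in c.member_ids):
            co_clustered += len(mem_pro)
            co_clustered_clusters += 1
        elif len(c.member_ids) == 1:
            singleton += 1
        else:
            prophage_only += len(mem_pro)
    n = co_clustered + singleton + prophage_only
    def pct(x: int) -> float | None:
        return 100.0 * x / n if n else None
    return {
        "n_prophages": n,
        "n_clusters": len(clusters),
        "co_clustered": co_clustered,
        "co_clustered_percent": pct(co_clustered),
        "co_clustered_clusters": co_clustered_clusters,
        "singleton": singleton,
        "singleton_percent": pct(singleton),
        "prophage_only": prophage_only,
        "prophage_only_percent": pct(prophage_only),
    }
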