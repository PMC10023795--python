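"""Alignment-free phylogeny from k-mer composition.

Each genome is summarized as its k-mer frequency profile (overlapping
windows on the given strand, 4^k lexicographically ordered features,
default k=4).  Pairwise dissimilarity is the Jensen–Shannon divergence
(base 2, so bounded in [0, 1]) or its square root, which is a true metric.
A rooted ultrametric tree is built by UPGMA (average linkage with
proportional averaging); neighbor joining is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio import TreeNode
from skbio.tree import nj

from ._kmers import encode_kmers, revcomp_codes

DEFAULT_K = 4


@dataclass(frozen=True)
class KmerProfile:
    """Normalized k-mer frequency vector of one sequence."""

    sequence_id: str
    k: int
    freqs: np.ndarray  # length 4^k, sums to 1

    def __post_init__(self) -> None:
        if self.freqs.shape != (4 ** self.k,):
            raise ValueError(f"profile must have length 4^{self.k}")
        if not np.isclose(self.freqs.sum(), 1.0, atol=1e-9):
            raise ValueError("profile frequencies must sum to 1")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal over labeled ids."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("diagonal is not zero")


@dataclass(frozen=True)
class PhyloTree:
    """Rooted tree with branch lengths; ``heights`` maps internal merges to
    ultrametric node heights when built by UPGMA."""

    root: TreeNode

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.root.tips()}


def kmer_profile(
    sequence_id: str,
    sequence: str,
    k: int = DEFAULT_K,
    symmetrize: bool = False,
) -> KmerProfile:
    """k-mer frequency profile over valid overlapping windows.

    Windows containing ambiguity codes are skipped.  With ``symmetrize`` the
    profile is averaged with the reverse-complement strand's profile.
    """
    if not 1 <= k <= 8:
        raise ValueError("k must be in [1, 8]")
    if len(sequence) < k:
        raise ValueError(f"sequence {sequence_id!r} too short for k={k}")
    codes = encode_kmers(sequence, k)
    if codes.size == 0:
        raise ValueError(f"sequence {sequence_id!r} has no ambiguity-free window of length {k}")
    counts = np.bincount(codes, minlength=4 ** k).astype(float)
    if symmetrize:
        counts += np.bincount(revcomp_codes(codes, k), minlength=4 ** k)
    return KmerProfile(sequence_id, k, counts / counts.sum())


def jsd(p: KmerProfile, q: KmerProfile) -> float:
    """Jensen–Shannon divergence, base 2: ``H(M) - (H(P)+H(Q))/2`` with
    ``M = (P+Q)/2``; in [0, 1], zero iff the profiles coincide."""
    if p.k != q.k:
        raise ValueError(f"mismatched k: {p.k} vs {q.k}")
    # scipy returns the JS *distance* (square root of the divergence)
    val = jensenshannon(p.freqs, q.freqs, base=2) ** 2
    return float(min(1.0, max(0.0, 0.0 if np.isnan(val) else val)))


def distance_matrix(
    profiles: Sequence[KmerProfile],
    metric: str = "jsd",
) -> DistanceMatrix:
    """All-pairs JSD (or sqrt-JSD, a true metric) over equal-k profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    if metric not in ("jsd", "sqrt_jsd"):
        raise ValueError(f"unknown metric {metric!r}")
    ids = tuple(p.sequence_id for p in profiles)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    ks = {p.k for p in profiles}
    if len(ks) != 1:
        raise ValueError(f"profiles have mixed k: {sorted(ks)}")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = jsd(profiles[i], profiles[j])
            if metric == "sqrt_jsd":
                v = float(np.sqrt(v))
            d[i, j] = d[j, i] = v
    return DistanceMatrix(ids, d)


def upgma(matrix: DistanceMatrix) -> PhyloTree:
    """UPGMA with proportional (size-weighted) averaging.

    Node heights are half the merge distance; a child's branch length is the
    parent height minus the child height.  Ties in the minimum distance are
    broken by the smallest (i, j) index pair in current cluster order, which
    makes the topology deterministic.
    """
    n = len(matrix.ids)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if np.isnan(matrix.d).any():
        raise ValueError("distance matrix contains NaN")
    d = matrix.d.astype(float)
    active = list(range(n))
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    node_of = {i: TreeNode(name=name) for i, name in enumerate(matrix.ids)}
    height_of = {i: 0.0 for i in range(n)}
    size_of = {i: 1 for i in range(n)}
    first_leaf = {i: i for i in range(n)}  # orders children in the written tree

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = dist[frozenset((i, j))]
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        dmin, ai, aj = best
        i, j = active[ai], active[aj]
        h = dmin / 2.0
        if first_leaf[j] < first_leaf[i]:
            i, j = j, i
        left, right = node_of[i], node_of[j]
        left.length = max(0.0, h - height_of[i])
        right.length = max(0.0, h - height_of[j])
        parent = TreeNode(children=[left, right])
        node_of[next_id] = parent
        height_of[next_id] = h
        size_of[next_id] = size_of[i] + size_of[j]
        first_leaf[next_id] = min(first_leaf[i], first_leaf[j])
        # proportional averaging of distances to the merged cluster
        for k_ in active:
            if k_ in (i, j):
                continue
            dik = dist[frozenset((i, k_))]
            djk = dist[frozenset((j, k_))]
            dist[frozenset((next_id, k_))] = (
                size_of[i] * dik + size_of[j] * djk
            ) / (size_of[i] + size_of[j])
        active = [a for a in active if a not in (i, j)] + [next_id]
        next_id += 1

    root = node_of[active[0]]
    root.length = None
    return PhyloTree(root)


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining alternative (non-ultrametric), via scikit-bio."""
    sk = SkbioDistanceMatrix(matrix.d, ids=list(matrix.ids))
    return PhyloTree(nj(sk))


def build_tree(matrix: DistanceMatrix, method: str = "upgma") -> PhyloTree:
    if method == "upgma":
        return upgma(matrix)
    if method == "nj":
        return neighbor_joining(matrix)
    raise ValueError(f"unknown tree method {method!r}")


def clade_recovery_check(tree: PhyloTree, planted_groups: Mapping[str, set[str]]) -> float:
    """Fraction of planted groups that are exactly monophyletic in the tree.

    A group is recovered iff some node's tip set equals the group.  Every
    leaf must belong to exactly one group.
    """
    leaves = tree.leaf_names()
    assigned: set[str] = set()
    for name, group in planted_groups.items():
        dupes = assigned & group
        if dupes:
            raise ValueError(f"leaves in multiple groups: {sorted(dupes)}")
        assigned |= group
    stray = leaves - assigned
    if stray:
        raise ValueError(f"leaves not in any planted group: {sorted(stray)}")

    tip_sets = {frozenset(t.name for t in node.tips()) or frozenset({node.name})
                for node in tree.root.traverse()}
    # single leaves count as (trivially monophyletic) tip sets too
    tip_sets |= {frozenset({name}) for name in leaves}
    hits = sum(1 for group in planted_groups.values() if frozenset(group) in tip_sets)
    return hits / len(planted_groups) if planted_groups else float("nan")


def write_distance_matrix(matrix: DistanceMatrix, path) -> None:
    """Square TSV with a header row/column of ids."""
    import pandas as pd

    pd.DataFrame(matrix.d, index=list(matrix.ids), columns=list(matrix.ids)).to_csv(
        path, sep="\t", index_label="id"
    )
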