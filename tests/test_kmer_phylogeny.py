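import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from prophagekit import kmer_phylogeny as kp
from prophagekit.synthetic_data import generate_host, mutate


def profile_from_freqs(sid, freqs, k=1):
    return kp.KmerProfile(sid, k, np.asarray(freqs, dtype=float))


def entropy_jsd_oracle(p, q):
    """Direct H(M) - (H(P)+H(Q))/2 with base-2 entropies; 0*log0 = 0."""
    def h(v):
        v = v[v > 0]
        return float(-(v * np.log2(v)).sum())
    m = (p + q) / 2
    return h(m) - (h(p) + h(q)) / 2


class TestKmerProfile:
    def test_homopolymer(self):
        prof = kp.kmer_profile("s", "AAAA", k=2)
        assert prof.freqs[0] == 1.0 and prof.freqs.sum() == 1.0

    def test_k1_uniform(self):
        prof = kp.kmer_profile("s", "ACGT", k=1)
        assert np.allclose(prof.freqs, [0.25, 0.25, 0.25, 0.25])

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            kp.kmer_profile("s", "ACG", k=4)

    def test_ambiguity_windows_skipped(self):
        prof = kp.kmer_profile("s", "AANAA", k=2)
        assert prof.freqs[0] == 1.0  # only the two AA windows count

    def test_self_concatenation_near_invariance(self):
        seq = generate_host(5000, 50.0, seed=3, replicon_id="s").sequence
        p1 = kp.kmer_profile("a", seq, k=4)
        p2 = kp.kmer_profile("b", seq + seq, k=4)
        tol = 1.0 / (len(seq) - 3)
        assert np.abs(p1.freqs - p2.freqs).max() <= 2 * tol


class TestJsd:
    def test_identity_is_zero(self):
        p = profile_from_freqs("p", [0.25, 0.25, 0.25, 0.25])
        q = profile_from_freqs("q", [0.25, 0.25, 0.25, 0.25])
        assert kp.jsd(p, q) == 0.0

    def test_disjoint_support_is_one(self):
        p = profile_from_freqs("p", [0.5, 0.5, 0, 0])
        q = profile_from_freqs("q", [0, 0, 0.5, 0.5])
        assert kp.jsd(p, q) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # P=(1,0), Q=(0.5,0.5): JSD = H(0.75,0.25) - 1/2 = 0.311278
        p = profile_from_freqs("p", [1.0, 0.0, 0.0, 0.0])
        q = profile_from_freqs("q", [0.5, 0.5, 0.0, 0.0])
        assert kp.jsd(p, q) == pytest.approx(0.311278, abs=1e-6)

    def test_mismatched_k_is_error(self):
        p = profile_from_freqs("p", [1.0, 0, 0, 0], k=1)
        q = profile_from_freqs("q", np.full(16, 1 / 16), k=2)
        with pytest.raises(ValueError, match="mismatched k"):
            kp.jsd(p, q)

    def test_matches_entropy_oracle_and_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.dirichlet(np.ones(4))
            b = rng.dirichlet(np.ones(4))
            p, q = profile_from_freqs("p", a), profile_from_freqs("q", b)
            assert kp.jsd(p, q) == pytest.approx(entropy_jsd_oracle(a, b), abs=1e-12)
            assert kp.jsd(p, q) == pytest.approx(kp.jsd(q, p))
            assert 0.0 <= kp.jsd(p, q) <= 1.0


class TestDistanceMatrix:
    def test_identical_sequences_zero_off_diagonal(self):
        seq = generate_host(2000, 50.0, seed=1, replicon_id="x").sequence
        profiles = [kp.kmer_profile("a", seq), kp.kmer_profile("b", seq)]
        dm = kp.distance_matrix(profiles)
        assert dm.d[0, 1] == 0.0

    def test_duplicate_ids_error(self):
        seq = "ACGTACGTACGT"
        with pytest.raises(ValueError, match="duplicate"):
            kp.distance_matrix([kp.kmer_profile("a", seq), kp.kmer_profile("a", seq)])

    def test_symmetric_zero_diagonal_random(self):
        rng = np.random.default_rng(2)
        profiles = [
            kp.kmer_profile(f"s{i}", generate_host(3000, 50.0, seed=rng,
                                                   replicon_id=f"s{i}").sequence)
            for i in range(5)
        ]
        dm = kp.distance_matrix(profiles)
        assert np.allclose(dm.d, dm.d.T) and np.allclose(np.diag(dm.d), 0)

    def test_sqrt_jsd_triangle_inequality(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            freqs = rng.dirichlet(np.ones(4), size=3)
            profs = [profile_from_freqs(f"p{i}", freqs[i]) for i in range(3)]
            dm = kp.distance_matrix(profs, metric="sqrt_jsd")
            for i, j, l in itertools.permutations(range(3), 3):
                assert dm.d[i, j] <= dm.d[i, l] + dm.d[l, j] + 1e-12


class TestUpgma:
    def test_hand_computed_three_taxa(self, tmp_path):
        dm = kp.DistanceMatrix(("A", "B", "C"), np.array(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]]))
        tree = kp.upgma(dm)
        from prophagekit.genome_io import write_newick
        out = tmp_path / "t.nwk"
        write_newick(tree, out)
        assert out.read_text().strip() == "((A:0.1,B:0.1):0.2,C:0.3);"

    def test_two_leaves(self, tmp_path):
        dm = kp.DistanceMatrix(("A", "B"), np.array([[0.0, 0.1], [0.1, 0.0]]))
        tree = kp.upgma(dm)
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths == {"A": pytest.approx(0.05), "B": pytest.approx(0.05)}

    def test_all_zero_distances(self):
        dm = kp.DistanceMatrix(("A", "B", "C"), np.zeros((3, 3)))
        tree = kp.upgma(dm)
        assert all(t.length == 0.0 for t in tree.root.tips())

    def test_nan_is_error(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        dm = kp.DistanceMatrix.__new__(kp.DistanceMatrix)
        object.__setattr__(dm, "ids", ("A", "B"))
        object.__setattr__(dm, "d", d)
        with pytest.raises(ValueError, match="NaN"):
            kp.upgma(dm)

    def test_matches_scipy_average_linkage_cophenetics(self):
        # independent oracle: scipy's average linkage cophenetic distances
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            cond = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
            square = squareform(cond)
            ids = tuple(f"t{i}" for i in range(n))
            tree = kp.upgma(kp.DistanceMatrix(ids, square))
            coph_ours = np.zeros_like(square)
            tips = {t.name: t for t in tree.root.tips()}
            for i in range(n):
                for j in range(i + 1, n):
                    d = tips[ids[i]].distance(tips[ids[j]])
                    coph_ours[i, j] = coph_ours[j, i] = d
            coph_scipy = squareform(cophenet(average(cond)))
            assert np.allclose(coph_ours, coph_scipy, atol=1e-10)

    def test_ultrametric_input_recovers_topology(self):
        # tree ((A,B),(C,D)): within-pair distance 0.2, across 0.8
        d = np.array([
            [0.0, 0.2, 0.8, 0.8],
            [0.2, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.2],
            [0.8, 0.8, 0.2, 0.0],
        ])
        tree = kp.upgma(kp.DistanceMatrix(("A", "B", "C", "D"), d))
        tip_sets = {frozenset(t.name for t in n.tips())
                    for n in tree.root.non_tips()}
        assert {frozenset({"A", "B"}), frozenset({"C", "D"})} <= tip_sets


class TestNeighborJoining:
    def test_leaf_set_preserved(self):
        rng = np.random.default_rng(3)
        profiles = [
            kp.kmer_profile(f"s{i}", generate_host(2000, 50.0, seed=rng,
                                                   replicon_id=f"s{i}").sequence)
            for i in range(4)
        ]
        tree = kp.build_tree(kp.distance_matrix(profiles), method="nj")
        assert tree.leaf_names() == {f"s{i}" for i in range(4)}


class TestCladeRecovery:
    def _tree(self, newick):
        from io import StringIO
        from skbio import TreeNode
        return kp.PhyloTree(TreeNode.read(StringIO(newick)))

    def test_perfect_recovery(self):
        t = self._tree("((A,B),(C,D));")
        assert kp.clade_recovery_check(t, {"g1": {"A", "B"}, "g2": {"C", "D"}}) == 1.0

    def test_crossed_groups_zero(self):
        t = self._tree("((A,C),(B,D));")
        assert kp.clade_recovery_check(t, {"g1": {"A", "B"}, "g2": {"C", "D"}}) == 0.0

    def test_unassigned_leaf_is_error(self):
        t = self._tree("((A,B),(C,D));")
        with pytest.raises(ValueError, match="not in any"):
            kp.clade_recovery_check(t, {"g1": {"A", "B"}, "g2": {"C"}})

    def test_planted_clades_recovered_from_mutated_descendants(self):
        rng = np.random.default_rng(19)
        profiles, groups = [], {}
        for i in range(3):
            anc = generate_host(30_000, 64.0, seed=rng,
                                replicon_id=f"anc{i}").sequence
            groups[f"g{i}"] = set()
            for j in range(4):
                name = f"anc{i}_d{j}"
                profiles.append(kp.kmer_profile(name, mutate(anc, 0.02, rng), k=4))
                groups[f"g{i}"].add(name)
        tree = kp.upgma(kp.distance_matrix(profiles))
        assert kp.clade_recovery_check(tree, groups) == 1.0
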