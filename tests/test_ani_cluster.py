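import math

import numpy as np
import pytest

from prophagekit import ani_cluster as ac
from prophagekit._kmers import decode_kmer
from prophagekit.synthetic_data import generate_host, mutate


class TestSketch:
    def test_palindromic_kmer_is_own_canonical(self):
        sk = ac.sketch("s", "ACGT", k=4)
        assert sk.n_kmers == 1
        assert decode_kmer(int(sk.kmers[0]), 4) == "ACGT"

    def test_repeated_kmer_counted_once(self):
        sk = ac.sketch("s", "AAAAA", k=4)
        assert sk.n_kmers == 1
        assert decode_kmer(int(sk.kmers[0]), 4) == "AAAA"

    def test_canonicalization_uses_reverse_complement(self):
        # TTTT canonicalizes to AAAA
        a = ac.sketch("a", "TTTT", k=4)
        b = ac.sketch("b", "AAAA", k=4)
        assert np.array_equal(a.kmers, b.kmers)

    def test_ambiguity_windows_excluded(self):
        sk = ac.sketch("s", "ACNGT", k=4)
        assert sk.n_kmers == 0

    def test_too_short_is_error(self):
        with pytest.raises(ValueError, match="shorter than k"):
            ac.sketch("s", "ACG", k=4)


def fake_sketch(sid, codes, length, k=21):
    return ac.KmerSketch(sid, k, np.array(sorted(codes), dtype=np.int64), length)


class TestEstimateAni:
    def test_identical_sketches(self):
        a = ac.sketch("a", "ACGTACGGTTACGA" * 10, k=8)
        b = ac.KmerSketch("b", 8, a.kmers, a.seq_length)
        est = ac.estimate_ani(a, b)
        assert est.ani == 1.0 and est.containment == 1.0

    def test_disjoint_sketches(self):
        est = ac.estimate_ani(fake_sketch("a", [0, 1], 100),
                              fake_sketch("b", [2, 3], 100))
        assert est.ani == 0.0 and est.containment == 0.0

    def test_mash_formula_at_jaccard_half(self):
        # j = 0.5 at k=21: d = ln(1.5)/21 = 0.019308, ani = 0.980692
        a = fake_sketch("a", [0, 1, 2], 100)
        b = fake_sketch("b", [0, 1, 3], 100)  # inter 2, union 4 -> j = 0.5
        est = ac.estimate_ani(a, b)
        assert est.ani == pytest.approx(1 - math.log(1.5) / 21, abs=1e-6)
        assert est.ani == pytest.approx(0.980692, abs=1e-6)

    def test_mismatched_k_is_error(self):
        with pytest.raises(ValueError, match="mismatched k"):
            ac.estimate_ani(fake_sketch("a", [0], 50, k=16),
                            fake_sketch("b", [0], 50, k=21))

    def test_empty_sketch_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            ac.estimate_ani(fake_sketch("a", [], 50), fake_sketch("b", [0], 50))

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        host = generate_host(5000, 50.0, seed=rng, replicon_id="h")
        a = ac.sketch("a", host.sequence, k=16)
        b = ac.sketch("b", mutate(host.sequence, 0.05, rng), k=16)
        assert ac.estimate_ani(a, b).ani == pytest.approx(ac.estimate_ani(b, a).ani)

    def test_parameter_recovery_at_2_percent(self):
        rng = np.random.default_rng(17)
        seq = generate_host(100_000, 60.0, seed=rng, replicon_id="h").sequence
        est = ac.estimate_ani(ac.sketch("orig", seq, 16),
                              ac.sketch("mut", mutate(seq, 0.02, rng), 16))
        assert 0.975 <= est.ani <= 0.985  # truth 0.98

    def test_monotone_decreasing_in_mutation_rate(self):
        rng = np.random.default_rng(23)
        seq = generate_host(30_000, 55.0, seed=rng, replicon_id="h").sequence
        base = ac.sketch("base", seq, 16)
        anis = [
            ac.estimate_ani(base, ac.sketch(f"m{r}", mutate(seq, r, 99), 16)).ani
            for r in (0.0, 0.01, 0.03, 0.08, 0.15)
        ]
        assert anis == sorted(anis, reverse=True)
        assert anis[0] == 1.0


def naive_greedy_oracle(sketches, ani_min=0.95, containment_min=0.80):
    """Re-implementation of the greedy rule over a precomputed full pairwise
    matrix; independent of the production code path."""
    pairs = {}
    for a in sketches:
        for b in sketches:
            if a.sequence_id != b.sequence_id:
                est = ac.estimate_ani(a, b)
                pairs[(a.sequence_id, b.sequence_id)] = est
    order = sorted(sketches, key=lambda s: (-s.seq_length, s.sequence_id))
    clusters = []  # [representative sketch, [members]]
    for sk in order:
        placed = False
        for rep, members in clusters:
            est = pairs[(sk.sequence_id, rep.sequence_id)]
            if est.ani >= ani_min and est.coverage >= containment_min:
                members.append(sk.sequence_id)
                placed = True
                break
        if not placed:
            clusters.append((sk, [sk.sequence_id]))
    return [(rep.sequence_id, tuple(members)) for rep, members in clusters]


class TestGreedyCluster:
    def test_all_dissimilar_are_singletons(self):
        rng = np.random.default_rng(1)
        sketches = [
            ac.sketch(f"s{i}", generate_host(3000, 50.0, seed=rng,
                                             replicon_id=f"s{i}").sequence, 16)
            for i in range(4)
        ]
        clusters = ac.greedy_cluster(sketches)
        assert all(len(c.member_ids) == 1 for c in clusters)

    def test_exact_duplicates_form_one_cluster(self):
        seq = generate_host(3000, 50.0, seed=2, replicon_id="x").sequence
        sketches = [ac.sketch(f"d{i}", seq, 16) for i in range(3)]
        (cluster,) = ac.greedy_cluster(sketches)
        assert set(cluster.member_ids) == {"d0", "d1", "d2"}
        assert cluster.representative_id == "d0"  # length tie broken by id

    def test_hand_traced_chain(self):
        # A-B similar, B-C similar, A-C not: C compared to representative A only
        common_abc = range(0, 326)
        ab_only = range(326, 620)
        bc_only = range(1000, 1294)
        a_only = range(2000, 2380)
        b_only = range(3000, 3086)
        c_only = range(4000, 4380)
        a = fake_sketch("A", [*common_abc, *ab_only, *a_only], 10_000, k=16)
        b = fake_sketch("B", [*common_abc, *ab_only, *bc_only, *b_only], 9_000, k=16)
        c = fake_sketch("C", [*common_abc, *bc_only, *c_only], 8_000, k=16)
        assert ac.estimate_ani(a, b).ani > 0.95
        assert ac.estimate_ani(b, c).ani > 0.95
        assert ac.estimate_ani(a, c).ani < 0.95
        clusters = ac.greedy_cluster([a, b, c])
        assert [set(cl.member_ids) for cl in clusters] == [{"A", "B"}, {"C"}]

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n_base = int(rng.integers(2, 5))
            bases = [generate_host(int(rng.integers(2000, 5000)), 50.0, seed=rng,
                                   replicon_id=f"b{i}").sequence
                     for i in range(n_base)]
            sketches = []
            for i in range(int(rng.integers(3, 13))):
                src = bases[int(rng.integers(n_base))]
                rate = float(rng.choice([0.0, 0.01, 0.02, 0.1]))
                seq = mutate(src, rate, rng)[: int(rng.integers(1500, len(src) + 1))]
                sketches.append(ac.sketch(f"s{i}", seq, 16))
            ours = [(c.representative_id, c.member_ids)
                    for c in ac.greedy_cluster(sketches)]
            assert ours == naive_greedy_oracle(sketches)

    def test_partition_and_removal_stability(self):
        rng = np.random.default_rng(41)
        base = generate_host(4000, 55.0, seed=rng, replicon_id="b").sequence
        sketches = [ac.sketch("long", base, 16),
                    ac.sketch("copy", mutate(base, 0.01, rng), 16),
                    ac.sketch("far", generate_host(3500, 55.0, seed=rng,
                                                   replicon_id="f").sequence, 16)]
        clusters = ac.greedy_cluster(sketches)
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(s.sequence_id for s in sketches)
        # removing a non-representative member leaves other assignments alone
        reps = {c.representative_id for c in clusters}
        (non_rep,) = [m for m in members if m not in reps]
        without = ac.greedy_cluster([s for s in sketches if s.sequence_id != non_rep])
        assert [c.representative_id for c in without] == \
            [c.representative_id for c in clusters]


class TestClusterSummary:
    def cluster(self, cid, rep, members):
        return ac.GenomeCluster(cid, rep, tuple(members))

    def test_hand_counts(self):
        clusters = [self.cluster("c1", "pro1", ["pro1", "phageX"]),
                    self.cluster("c2", "pro2", ["pro2"]),
                    self.cluster("c3", "pro3", ["pro3", "pro4"])]
        s = ac.cluster_summary(clusters, ["pro1", "pro2", "pro3", "pro4"], ["phageX"])
        assert (s["co_clustered"], s["singleton"], s["prophage_only"]) == (1, 1, 2)
        assert s["co_clustered"] + s["singleton"] + s["prophage_only"] == s["n_prophages"]

    def test_no_phages(self):
        s = ac.cluster_summary([self.cluster("c1", "p1", ["p1"])], ["p1"], [])
        assert s["co_clustered"] == 0

    def test_unlabeled_member_is_error(self):
        with pytest.raises(ValueError, match="mystery"):
            ac.cluster_summary([self.cluster("c1", "mystery", ["mystery"])], [], [])
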