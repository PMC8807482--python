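"""Cross-repertoire statistics: Jaccard, sharing spectrum, Venn, consensus, UPGMA."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bcrep.clonotypes import ClonotypeTable
from bcrep.compare import (build_tree, consensus_profile, jaccard,
                           modal_length_stratum, repertoire_distance,
                           sharing_spectrum, venn3)

sets_st = st.sets(st.text(alphabet="ACDW", min_size=1, max_size=4), max_size=12)


class TestJaccard:
    @pytest.mark.parametrize("a,b,expect", [
        ({"x", "y"}, {"x", "y"}, 1.0),
        ({"x"}, {"y"}, 0.0),
        ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
        (set(), set(), 0.0),
    ])
    def test_examples(self, a, b, expect):
        assert jaccard(a, b) == pytest.approx(expect)

    @given(sets_st, sets_st)
    def test_bounds_and_symmetry(self, a, b):
        j = jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard(b, a)

    @given(sets_st, sets_st, sets_st)
    def test_distance_triangle_inequality(self, a, b, c):
        d = lambda x, y: 1.0 - jaccard(x, y)
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-12


class TestSharing:
    def test_full_overlap(self):
        s = {"a", "b", "c"}
        r = sharing_spectrum({"r1": s, "r2": set(s), "r3": set(s)})
        assert r.shared_percent(2) == 100.0

    def test_disjoint(self):
        r = sharing_spectrum({"r1": {"a"}, "r2": {"b"}, "r3": {"c"}})
        assert r.shared_percent(2) == 0.0

    def test_spiked_publics_recovered_exactly(self):
        """Disjoint privates + publics in every repertoire: the top-shared set
        at full occupancy is exactly the spike-in."""
        publics = {"CARDYYGSSW", "CARGGYDGYW", "CTRDNWDAYF", "CARSSGYWYF", "CARDGTTGTW"}
        reps = {f"s{i}": publics | {f"priv_{i}_{k}" for k in range(30)} for i in range(8)}
        r = sharing_spectrum(reps, top_threshold=6)
        assert set(r.top_shared) == publics
        assert all(r.occupancy[p] == 8 for p in publics)

    def test_fraction_one_at_k1_and_monotone(self):
        r = sharing_spectrum({"a": {"x", "y"}, "b": {"y", "z"}, "c": {"z"}})
        ks = sorted(r.shared_fraction_at_k)
        assert r.shared_fraction_at_k[1] == 1.0
        fracs = [r.shared_fraction_at_k[k] for k in ks]
        assert all(f1 >= f2 for f1, f2 in zip(fracs, fracs[1:]))

    @given(st.dictionaries(st.sampled_from("abcd"), sets_st, min_size=2, max_size=4))
    def test_monotone_property(self, reps):
        if sum(len(s) for s in reps.values()) == 0:
            return
        r = sharing_spectrum(reps)
        ks = sorted(r.shared_fraction_at_k)
        fracs = [r.shared_fraction_at_k[k] for k in ks]
        assert all(f1 >= f2 for f1, f2 in zip(fracs, fracs[1:]))

    def test_requires_two_repertoires(self):
        with pytest.raises(ValueError):
            sharing_spectrum({"only": {"a"}})


class TestVenn:
    def test_identity(self):
        s = {"a", "b", "c"}
        v = venn3(s, set(s), set(s))
        assert v.regions["111"] == 3
        assert sum(v.regions.values()) == 3

    def test_disjoint(self):
        v = venn3({"a"}, {"b"}, {"c"})
        assert v.regions["100"] == v.regions["010"] == v.regions["001"] == 1
        assert v.regions["111"] == 0

    def test_matches_membership_pattern_oracle(self):
        rng = np.random.default_rng(3)
        symbols = [f"x{i}" for i in range(100)]
        for _ in range(20):
            a, b, c = (set(rng.choice(symbols, size=50, replace=False)) for _ in range(3))
            v = venn3(a, b, c)
            oracle = {}
            for x in a | b | c:
                key = f"{int(x in a)}{int(x in b)}{int(x in c)}"
                oracle[key] = oracle.get(key, 0) + 1
            for k, n in v.regions.items():
                assert n == oracle.get(k, 0)
            assert v.union_size == len(a | b | c)
            assert v.pairwise[("A", "B")] == len(a & b)


class TestConsensus:
    def test_unanimity(self):
        p = consensus_profile(["CARDYYGSWF"] * 10)
        assert p.consensus == "CARDYYGSWF"
        assert p.conservation == [1.0] * 10

    def test_tie_breaks_lexicographically(self):
        p = consensus_profile(["CARDY", "CARDF"])
        assert p.consensus == "CARDF"
        assert p.conservation == [1.0, 1.0, 1.0, 1.0, 0.5]

    def test_single_sequence(self):
        p = consensus_profile(["CW"])
        assert p.consensus == "CW" and p.conservation == [1.0, 1.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_profile([])

    def test_mixed_lengths_direct_to_stratification(self):
        with pytest.raises(ValueError, match="stratify"):
            consensus_profile(["CW", "CAW"])

    def test_modal_stratum(self):
        seqs = ["CAW", "CDW", "CAAW", "CW"]
        assert modal_length_stratum(seqs) == ["CAW", "CDW"]


class TestDistanceAndTree:
    def test_duplicate_repertoires_are_zero_distance(self):
        labels, D = repertoire_distance({"a": {"x", "y"}, "b": {"x", "y"}})
        assert D[0, 1] == 0.0

    def test_disjoint_maximal(self):
        labels, D = repertoire_distance({"a": {"x"}, "b": {"y"}})
        assert D[0, 1] == 1.0

    def test_hand_computed_matrix(self):
        reps = {"r1": {"a", "b"}, "r2": {"b", "c"}, "r3": {"a", "b", "c", "d"}}
        labels, D = repertoire_distance(reps)
        assert D[0, 1] == pytest.approx(1 - 1 / 3)
        assert D[0, 2] == pytest.approx(1 - 2 / 4)
        assert D[1, 2] == pytest.approx(1 - 2 / 4)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_bray_curtis_on_tables(self):
        t1 = ClonotypeTable("r1", "cdr3_aa", {"a": 8, "b": 2}, 10)
        t2 = ClonotypeTable("r2", "cdr3_aa", {"a": 2, "b": 8}, 10)
        labels, D = repertoire_distance({"r1": t1, "r2": t2}, metric="bray_curtis")
        assert D[0, 1] == pytest.approx(0.6)  # 1 - 2*(0.2+0.2)/2

    def test_upgma_hand_case(self):
        D = np.array([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
        t = build_tree(D, ["A", "B", "C"])
        assert "(A:0.1,B:0.1)" in t.newick
        assert t.linkage[0, 2] == pytest.approx(0.2)  # A-B merge at height 0.1

    def test_two_leaves(self):
        t = build_tree(np.array([[0.0, 0.5], [0.5, 0.0]]), ["A", "B"])
        assert t.newick == "(A:0.25,B:0.25);"

    def test_label_permutation_isomorphism(self):
        import dendropy

        rng = np.random.default_rng(7)
        M = rng.random((5, 5))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        labels = ["a", "b", "c", "d", "e"]
        perm = [3, 1, 4, 0, 2]
        t1 = build_tree(M, labels)
        t2 = build_tree(M[np.ix_(perm, perm)], [labels[i] for i in perm])
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.newick, schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.newick, schema="newick", taxon_namespace=tns)
        assert dendropy.calculate.treecompare.symmetric_difference(d1, d2) == 0

    def test_newick_parses_to_same_leaves_and_is_ultrametric(self):
        import dendropy

        rng = np.random.default_rng(11)
        M = rng.random((6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        labels = [f"rep{i}" for i in range(6)]
        t = build_tree(M, labels)
        tree = dendropy.Tree.get(data=t.newick, schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == labels
        tree.calc_node_root_distances()
        depths = [l.root_distance for l in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_matches_scipy_average_linkage_oracle(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(2)
        for _ in range(25):
            M = rng.random((6, 6))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0)
            mine = build_tree(M, [str(i) for i in range(6)])
            ref = linkage(squareform(M), method="average")
            assert np.allclose(cophenet(mine.linkage), cophenet(ref))

    def test_asymmetric_rejected(self):
        M = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError):
            build_tree(M, ["A", "B"])

    def test_single_repertoire_rejected(self):
        with pytest.raises(ValueError):
            repertoire_distance({"only": {"a"}})


class TestCorrelatedSwitching:
    def test_igg2b_2c_closer_than_igg1(self, small_cohort):
        """Under the class-switch model, IgG2b and IgG2c repertoires of a
        sample share clones with each other but only publics with IgG1."""
        _, _, _, truth = small_cohort
        grp = truth[(truth.group == "rna_loaded")]
        within, across = [], []
        for _, sub in grp.groupby("sample_id"):
            iso = {i: set(sub[sub.c_call == i].cdr3_aa) for i in ("IgG1", "IgG2b", "IgG2c")}
            within.append(jaccard(iso["IgG2b"], iso["IgG2c"]))
            across.append(jaccard(iso["IgG2b"], iso["IgG1"]))
            across.append(jaccard(iso["IgG2c"], iso["IgG1"]))
        assert np.mean(within) > np.mean(across)
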