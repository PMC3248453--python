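"""Alignment, trimming, concatenation, distances, NJ, rooting, components."""

import math
import warnings

import dendropy
import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from ltrcensus import (MSA, DistanceMatrix, concatenate, distance_matrix,
                       mantel_r, nj_tree, progressive_align,
                       root_with_outgroup, similarity_components,
                       trim_columns)
from ltrcensus.phylo import pairwise_score
from ltrcensus.seedbank import AMINO_ACIDS, _mutate_protein, _random_protein


def _biopython_nw_score(a, b):
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11
    al.extend_gap_score = -1
    return al.score(a, b)


class TestProgressiveAlign:
    def test_identical_pair_gap_free(self):
        msa = progressive_align({"a": "MKVLAW", "b": "MKVLAW"})
        assert msa.rows == ["MKVLAW", "MKVLAW"]

    @pytest.mark.parametrize("a,b", [
        ("HEAGAWGHEE", "PAWHEAE"),
        ("MKVLAWHEAGAWGHEE", "MKVLAW"),
        ("ACDEFGHIK", "ACDEFGHIK"),
    ])
    def test_pairwise_score_matches_independent_dp_oracle(self, a, b):
        assert pairwise_score(a, b) == pytest.approx(_biopython_nw_score(a, b))

    def test_single_sequence_noop(self):
        msa = progressive_align({"only": "MKV"})
        assert msa.taxa == ["only"] and msa.rows == ["MKV"]

    def test_family_alignment_keeps_high_identity(self):
        # 5% per copy from the ancestor ~ 10% pairwise divergence
        rng = np.random.default_rng(8)
        anc = _random_protein(rng, 120)
        seqs = {f"t{i}": _mutate_protein(rng, anc, 0.05) for i in range(5)}
        msa = progressive_align(seqs)
        for i in range(5):
            for j in range(i + 1, 5):
                a, b = msa.rows[i], msa.rows[j]
                same = sum(x == y and x != "-" for x, y in zip(a, b))
                assert same / len(a) >= 0.8

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            progressive_align({})


class TestTrimAndConcatenate:
    def test_gap_free_unchanged(self):
        msa = MSA(["a", "b"], ["MKV", "MRV"])
        assert trim_columns(msa, 0.5).rows == msa.rows

    def test_all_gap_column_always_removed(self):
        msa = MSA(["a", "b"], ["M-V", "M-V"])
        for thr in (0.0, 0.5, 0.99):
            assert trim_columns(msa, thr).rows == ["MV", "MV"]

    def test_gap_fraction_boundary(self):
        msa = MSA(list("abcd"), ["MKV", "M-V", "MKV", "MKV"])  # col 1: 1/4 gaps
        assert trim_columns(msa, 0.2).rows[0] == "MV"
        assert trim_columns(msa, 0.25).rows[0] == "MKV"

    def test_everything_trimmed_warns(self):
        msa = MSA(["a", "b"], ["-K", "K-"])
        with pytest.warns(UserWarning, match="all alignment columns"):
            out = trim_columns(msa, 0.0)
        assert out.n_columns == 0

    def test_concatenation_is_additive_and_ordered(self):
        lengths = [120, 95, 60, 40]
        rng = np.random.default_rng(3)
        blocks = [MSA(["x", "y"], [_random_protein(rng, L)] * 2)
                  for L in lengths]
        cat = concatenate(blocks)
        assert cat.n_columns == sum(lengths)
        assert cat.rows[0][:120] == blocks[0].rows[0]
        assert cat.rows[0][120:215] == blocks[1].rows[0]

    def test_missing_taxon_gets_gap_filler(self):
        b1 = MSA(["x", "y"], ["MKV", "MRV"])
        b2 = MSA(["x"], ["WWWW"])
        cat = concatenate([b1, b2])
        assert cat.row("y") == "MRV" + "----"

    def test_disjoint_taxa_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            concatenate([MSA(["a"], ["MK"]), MSA(["b"], ["MR"])])


class TestDistances:
    def test_identical_rows_zero(self):
        dm = distance_matrix(MSA(["a", "b"], ["MKVL", "MKVL"]), model="p")
        assert dm.matrix[0, 1] == 0.0

    def test_p_distance_direct_count(self):
        dm = distance_matrix(MSA(["a", "b"], ["AAAA", "AAAT"]), model="p")
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_poisson_closed_form(self):
        dm = distance_matrix(MSA(["a", "b"], ["AAAA", "AAAT"]), model="poisson")
        assert dm.matrix[0, 1] == pytest.approx(-math.log(0.75))

    def test_gap_only_overlap_names_the_pair(self):
        msa = MSA(["a", "b"], ["MK--", "--VL"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            distance_matrix(msa)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(MSA(["a", "b"], ["MK", "MK"]), model="lg")


def _random_additive(rng, n):
    """Random binary tree with uniform branch lengths; returns (taxa,
    path-distance matrix, newick)."""
    import itertools
    children = {}
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.1, 2.0, size=2)
        children[next_id] = [(a, la), (b, lb)]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    root = active[0]

    dist = {}

    def collect(node):
        if node < n:
            return {node: 0.0}
        sub = []
        for child, ln in children[node]:
            d = collect(child)
            sub.append({k: v + ln for k, v in d.items()})
        for x, y in itertools.combinations(range(len(sub)), 2):
            for u, du in sub[x].items():
                for v, dv in sub[y].items():
                    dist[(u, v)] = dist[(v, u)] = du + dv
        merged = {}
        for s in sub:
            merged.update(s)
        return merged

    collect(root)
    m = np.zeros((n, n))
    for (u, v), d in dist.items():
        m[u, v] = d

    def newick(node):
        if node < n:
            return f"t{node}"
        parts = [f"{newick(c)}:{ln:.10g}" for c, ln in children[node]]
        return "(" + ",".join(parts) + ")"

    return [f"t{i}" for i in range(n)], m, newick(root) + ";"


def _rf(newick_a, newick_b, taxa):
    tns = dendropy.TaxonNamespace(taxa)
    ta = dendropy.Tree.get(data=newick_a, schema="newick",
                           taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick",
                           taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


class TestNeighborJoining:
    def test_four_taxon_hand_matrix_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> additive matrix by path lengths
        taxa = list("ABCD")
        m = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], float)
        tree = nj_tree(DistanceMatrix(taxa, m))
        rec = tree.leaf_distances()
        perm = [rec.taxa.index(t) for t in taxa]
        assert np.allclose(rec.matrix[np.ix_(perm, perm)], m, atol=1e-12)
        assert _rf(tree.newick(), "((A:1,B:2):1,(C:3,D:1));", taxa) == 0

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABC"), m))
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 3.0, "C": 5.0})

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(list("ABC"),
                           np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]]))

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        taxa, m, true_newick = _random_additive(rng, n)
        tree = nj_tree(DistanceMatrix(taxa, m))
        rec = tree.leaf_distances()
        perm = [rec.taxa.index(t) for t in taxa]
        assert np.allclose(rec.matrix[np.ix_(perm, perm)], m, atol=1e-9)
        assert _rf(tree.newick(), true_newick, taxa) == 0

    def test_ultrametric_matches_single_linkage_topology(self):
        # ultrametric: ((A,B):1,(C,D):1) with heights 1 and 2
        taxa = list("ABCD")
        m = np.array([[0, 2, 4, 4],
                      [2, 0, 4, 4],
                      [4, 4, 0, 2],
                      [4, 4, 2, 0]], float)
        tree = nj_tree(DistanceMatrix(taxa, m))
        assert _rf(tree.newick(), "((A:1,B:1):1,(C:1,D:1));", taxa) == 0


class TestRooting:
    def _tree(self):
        taxa = list("ABCD")
        m = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], float)
        return nj_tree(DistanceMatrix(taxa, m))

    def test_single_outgroup_bisects_pendant_branch(self):
        rooted = root_with_outgroup(self._tree(), ["C"])
        kids = rooted.root.children
        names = [{lf.name for lf in k.leaves()} for k in kids]
        assert {"C"} in names
        c_branch = kids[names.index({"C"})]
        assert c_branch.length == pytest.approx(1.5)  # half of C's 3.0

    def test_outgroup_equals_all_taxa_rejected(self):
        with pytest.raises(ValueError):
            root_with_outgroup(self._tree(), list("ABCD"))

    def test_rooting_preserves_path_lengths(self):
        tree = self._tree()
        before = tree.leaf_distances()
        rooted = root_with_outgroup(tree, ["A", "B"])
        after = rooted.leaf_distances()
        perm = [after.taxa.index(t) for t in before.taxa]
        assert np.allclose(before.matrix, after.matrix[np.ix_(perm, perm)])

    def test_non_monophyletic_outgroup_warns(self):
        with pytest.warns(UserWarning, match="not monophyletic"):
            root_with_outgroup(self._tree(), ["A", "C"])


class TestSimilarityComponents:
    def _sets(self):
        from ltrcensus.seedbank import domain_ancestor
        rng = np.random.default_rng(9)
        seqs = {}
        for i in range(4):
            seqs[f"G{i}"] = _mutate_protein(rng, domain_ancestor("RT_RVT1"), 0.1)
            seqs[f"C{i}"] = _mutate_protein(rng, domain_ancestor("RT_RVT2"), 0.1)
        return seqs

    def test_superfamilies_separate_into_two_components(self):
        seqs = self._sets()
        comps = similarity_components(seqs, score_threshold=200.0)
        assert len(comps) == 2
        assert {c[0][0] for c in comps} == {"C", "G"}

    def test_threshold_above_max_gives_singletons(self):
        seqs = self._sets()
        comps = similarity_components(seqs, score_threshold=1e9)
        assert len(comps) == len(seqs)

    def test_matches_union_find_oracle(self):
        seqs = self._sets()
        thr = 200.0
        parent = {k: k for k in seqs}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        names = sorted(seqs)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if pairwise_score(seqs[a], seqs[b]) >= thr:
                    parent[find(a)] = find(b)
        oracle = {}
        for k in names:
            oracle.setdefault(find(k), []).append(k)
        expected = sorted((sorted(v) for v in oracle.values()),
                          key=lambda c: (-len(c), c[0]))
        assert similarity_components(seqs, thr) == expected


def test_mantel_r_on_known_matrices():
    t = list("abcd")
    m1 = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]], float)
    a = DistanceMatrix(t, m1)
    assert mantel_r(a, a) == pytest.approx(1.0)
    b = DistanceMatrix(t, m1 * 2.0)
    assert mantel_r(a, b) == pytest.approx(1.0)
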