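"""Distances, neighbor joining and bootstrap support."""
import numpy as np
import pytest

from conftest import least_squares_topology, tree_path_distances
from kunitzkit.io_formats import SequenceRecord
from kunitzkit.phylo import (
    DistanceMatrix,
    bootstrap_support,
    neighbor_joining,
    protein_distance,
)
from kunitzkit.synthetic_data import random_tree, substream


class TestProteinDistance:
    def _records(self, seqs):
        return [SequenceRecord(id=f"s{i}", residues=s) for i, s in enumerate(seqs)]

    def test_identical_pair_is_zero_under_both_models(self):
        recs = self._records(["MKLV" * 10, "MKLV" * 10])
        for model in ("p", "poisson"):
            assert protein_distance(recs, model=model).d[0, 1] == 0.0

    def test_counting_ten_differences_in_hundred_columns(self):
        a = "A" * 100
        b = "W" * 10 + "A" * 90
        dm = protein_distance(self._records([a, b]), model="p")
        assert dm.d[0, 1] == pytest.approx(0.1)

    def test_poisson_correction_closed_form(self):
        a = "A" * 100
        b = "W" * 10 + "A" * 90
        dm = protein_distance(self._records([a, b]), model="poisson")
        assert dm.d[0, 1] == pytest.approx(-np.log(0.9), rel=1e-12)

    def test_pairwise_deletion_of_gaps(self):
        recs = self._records(["AA-AA", "AAWAA", "AAAAW"])
        dm = protein_distance(recs, model="p")
        assert dm.d[0, 1] == 0.0  # gap column excluded pairwise
        assert dm.d[0, 2] == pytest.approx(0.25)

    def test_errors(self):
        with pytest.raises(ValueError, match="shared"):
            protein_distance(self._records(["A---", "-W--"]))
        with pytest.raises(ValueError, match="Poisson"):
            protein_distance(self._records(["AAAA", "WWWW"]), model="poisson")
        with pytest.raises(ValueError, match="equal length"):
            protein_distance(self._records(["AAA", "AAAA"]))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            labels=["a", "b", "c"],
            d=np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float),
        )
        tree = neighbor_joining(dm)
        lengths = {n.label: n.length for n in tree.root.children}
        assert lengths == {"a": 0.5, "b": 1.5, "c": 2.5}

    def test_requires_three_taxa(self):
        dm = DistanceMatrix(labels=["a", "b"], d=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_recovers_random_additive_trees_exactly(self, n_taxa):
        for s in range(25):
            truth = random_tree(n_taxa, seed=100 * n_taxa + s, length_range=(0.1, 1.0))
            labels, D = tree_path_distances(truth)
            nj = neighbor_joining(DistanceMatrix(labels=labels, d=D))
            assert nj.splits() == truth.splits()
            l2, D2 = tree_path_distances(nj)
            idx = [l2.index(l) for l in labels]
            assert np.allclose(D2[np.ix_(idx, idx)], D, atol=1e-9)

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_agrees_with_least_squares_oracle(self, n_taxa):
        for s in range(15):
            truth = random_tree(n_taxa, seed=7000 + 10 * n_taxa + s,
                                length_range=(0.1, 1.0))
            labels, D = tree_path_distances(truth)
            dm = DistanceMatrix(labels=labels, d=D)
            oracle_splits, rss = least_squares_topology(dm)
            assert rss < 1e-18
            assert neighbor_joining(dm).splits() == oracle_splits

    def test_equidistant_matrix_handled_deterministically(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(labels=list("abcd"), d=d)
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm)
        assert t1.newick() == t2.newick()
        internal = [
            n.length for n in t1.postorder()
            if n.parent is not None and not n.is_leaf()
        ]
        assert all(abs(l) < 1e-12 for l in internal)

    def test_leaf_set_and_branch_count(self):
        truth = random_tree(7, seed=9, length_range=(0.1, 1.0))
        labels, D = tree_path_distances(truth)
        nj = neighbor_joining(DistanceMatrix(labels=labels, d=D))
        assert sorted(nj.leaf_labels()) == sorted(labels)
        assert nj.n_branches() == 2 * len(labels) - 3

    def test_matches_independent_nj_implementation(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        for s in range(10):
            truth = random_tree(6, seed=3000 + s, length_range=(0.1, 1.0))
            labels, D = tree_path_distances(truth)
            mine = neighbor_joining(DistanceMatrix(labels=labels, d=D))
            sk = sk_nj(SkDM(D, ids=labels))
            all_l = frozenset(labels)
            ref = min(all_l)
            sk_splits = set()
            for node in sk.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = all_l - side
                if 1 < len(side) < len(all_l) - 1:
                    sk_splits.add(side)
            assert sk_splits == mine.splits()


class TestBootstrap:
    def _clade_alignment(self, n_cols=200, seed=0):
        """Two well-separated 3-taxon clades with clean column signal."""
        rng = substream(seed, "test/bootstrap")
        left = rng.choice(list("ACDEF"), size=n_cols)
        right = rng.choice(list("KLMNP"), size=n_cols)
        recs = []
        for i in range(3):
            noise = rng.random(n_cols) < 0.02
            seq = np.where(noise, "G", left)
            recs.append(SequenceRecord(id=f"L{i}", residues="".join(seq)))
        for i in range(3):
            noise = rng.random(n_cols) < 0.02
            seq = np.where(noise, "G", right)
            recs.append(SequenceRecord(id=f"R{i}", residues="".join(seq)))
        return recs

    def test_single_replicate_gives_binary_support(self):
        recs = self._clade_alignment(seed=1)
        tree = bootstrap_support(recs, n_reps=1, seed=2, model="p")
        supports = [
            n.support for n in tree.postorder()
            if n.parent is not None and not n.is_leaf() and n.support is not None
        ]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_clean_signal_gets_high_support(self):
        recs = self._clade_alignment(seed=3)
        tree = bootstrap_support(recs, n_reps=50, seed=4, model="p")
        all_l = frozenset(r.id for r in recs)
        ref = min(all_l)
        clade = frozenset(["L0", "L1", "L2"])
        key = all_l - clade if ref in clade else clade
        support = {
            (all_l - frozenset(l.label for l in n.leaves())
             if ref in frozenset(l.label for l in n.leaves())
             else frozenset(l.label for l in n.leaves())): n.support
            for n in tree.postorder()
            if n.parent is not None and not n.is_leaf()
        }
        assert support[key] >= 90.0

    def test_shuffled_columns_lose_support(self):
        rng = np.random.default_rng(5)
        recs = self._clade_alignment(seed=6)
        # permute residues within each sequence independently: no shared signal
        shuffled = [
            SequenceRecord(
                id=r.id,
                residues="".join(rng.permutation(list(r.residues))),
            )
            for r in recs
        ]
        tree = bootstrap_support(shuffled, n_reps=50, seed=7, model="p")
        supports = [
            n.support for n in tree.postorder()
            if n.parent is not None and not n.is_leaf() and n.support is not None
        ]
        assert np.median(supports) < 70.0
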