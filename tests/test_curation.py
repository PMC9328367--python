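"""Homolog curation: occupancy, trimming, masking, long tips, deep paralogs."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodiscord._trees import parse_newick, taxon_of
from phylodiscord.alignment import Alignment
from phylodiscord.curation import (
    cut_deep_paralogs,
    filter_cluster_occupancy,
    mask_same_taxon_tips,
    remove_spurious_tips,
    trim_columns,
)

from conftest import random_alignment


def uniform_aln(labels, seq="ACGT"):
    return Alignment.from_pairs([(l, seq) for l in labels])


class TestClusterOccupancy:
    def test_boundary_keep_and_discard(self):
        labels20 = [f"sp{i}@1" for i in range(20)]
        labels19 = [f"sp{i}@1" for i in range(19)]
        assert filter_cluster_occupancy(labels20, min_taxa=20)
        assert not filter_cluster_occupancy(labels19, min_taxa=20)

    def test_counts_distinct_taxa_not_sequences(self):
        labels = [f"sp1@{i}" for i in range(30)]  # 30 seqs, 1 taxon
        assert not filter_cluster_occupancy(labels, min_taxa=2)

    def test_batch_matches_recount_oracle(self, rng):
        for _ in range(1000):
            n_taxa = int(rng.integers(1, 30))
            labels = [
                f"sp{int(rng.integers(n_taxa))}@{j}"
                for j in range(int(rng.integers(1, 40)))
            ]
            expected = len({l.split("@")[0] for l in labels}) >= 10
            assert filter_cluster_occupancy(labels, 10) == expected


class TestTrimColumns:
    def test_strict_greater_than_boundary(self):
        """100% missing removed, exactly 90% retained at threshold 0.9."""
        aln = uniform_aln([f"r{i}" for i in range(10)], "AA")
        aln.data[:, 0] = b"-"
        aln.data[:9, 1] = b"-"
        out = trim_columns(aln, 0.9)
        assert out.n_cols == 1
        assert out.data[9, 0] == b"A"

    def test_no_missing_unchanged(self, rng):
        aln = random_alignment(rng, 8, 50, missing_frac=0.0)
        out = trim_columns(aln, 0.2)
        assert np.array_equal(out.data, aln.data)

    def test_idempotent(self, rng):
        aln = random_alignment(rng, 10, 100, missing_frac=0.3)
        once = trim_columns(aln, 0.2)
        twice = trim_columns(once, 0.2)
        assert np.array_equal(once.data, twice.data)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        rows=st.lists(
            st.text(alphabet="ACGT-N?", min_size=12, max_size=12),
            min_size=2, max_size=8,
        ),
        threshold=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_trim_properties_hold_for_any_alignment(self, rows, threshold):
        """Idempotence and monotone column count, for arbitrary inputs."""
        aln = Alignment.from_pairs((f"r{i}", s) for i, s in enumerate(rows))
        once = trim_columns(aln, threshold)
        twice = trim_columns(once, threshold)
        assert once.n_cols <= aln.n_cols
        assert np.array_equal(once.data, twice.data)
        assert once.labels == aln.labels

    def test_matches_per_column_recount(self, rng):
        aln = random_alignment(rng, 50, 200, missing_frac=0.25)
        out = trim_columns(aln, 0.2)
        kept = []
        for j in range(aln.n_cols):
            missing = sum(
                aln.data[i, j] in (b"-", b"N", b"?") for i in range(50)
            )
            if missing / 50 <= 0.2:
                kept.append(j)
        assert np.array_equal(out.data, aln.data[:, kept])


class TestMaskSameTaxonTips:
    def test_cherry_keeps_higher_character_tip(self):
        tree = parse_newick("((A@1:1,A@2:1):1,B@1:1);")
        aln = Alignment.from_pairs(
            [("A@1", "ACGTACGT"), ("A@2", "ACGT--NN"), ("B@1", "ACGTACGT")]
        )
        out = mask_same_taxon_tips(tree, aln)
        assert sorted(l.taxon.label for l in out.leaf_node_iter()) == ["A@1", "B@1"]

    def test_paraphyletic_grade_collapsed_on_rooted_tree(self):
        tree = parse_newick("((A@1:1,(A@2:1,B@1:1):1):1,C@1:1);", rooted=True)
        aln = uniform_aln(["A@1", "A@2", "B@1", "C@1"])
        out = mask_same_taxon_tips(tree, aln)
        labels = sorted(l.taxon.label for l in out.leaf_node_iter())
        assert labels == ["A@1", "B@1", "C@1"]

    def test_two_interposed_clades_untouched(self):
        tree = parse_newick(
            "((A@1:1,(B@1:1,(C@1:1,A@2:1):1):1):1,D@1:1);", rooted=True
        )
        aln = uniform_aln(["A@1", "A@2", "B@1", "C@1", "D@1"])
        out = mask_same_taxon_tips(tree, aln)
        assert len(out.leaf_nodes()) == 5

    def test_tip_missing_from_alignment_raises(self):
        tree = parse_newick("((A@1:1,A@2:1):1,B@1:1);")
        aln = uniform_aln(["A@1", "B@1"])
        with pytest.raises(KeyError):
            mask_same_taxon_tips(tree, aln)

    def test_simulated_trees_never_retain_same_taxon_cherry(self):
        """Injected sister duplicates are always masked."""
        py = random.Random(7)
        for rep in range(500):
            taxa = [f"sp{i}" for i in range(6)]
            labels = [f"{t}@1" for t in taxa]
            dup_taxon = py.choice(taxa)
            labels.append(f"{dup_taxon}@2")
            py.shuffle(labels)
            # random caterpillar with the duplicate adjacent to its twin
            nwk = labels[0]
            for lab in labels[1:]:
                nwk = f"({nwk}:1,{lab}:1)"
            tree = parse_newick(nwk + ";")
            aln = uniform_aln(labels)
            out = mask_same_taxon_tips(tree, aln)
            for nd in out.preorder_node_iter():
                kids = nd.child_nodes()
                if len(kids) == 2 and all(k.is_leaf() for k in kids):
                    t1, t2 = (taxon_of(k.taxon.label) for k in kids)
                    assert t1 != t2

    def test_tip_count_never_increases(self, rng):
        tree = parse_newick("(((A@1:1,B@1:1):1,(A@2:1,C@1:1):1):1,D@1:1);")
        aln = uniform_aln(["A@1", "A@2", "B@1", "C@1", "D@1"])
        out = mask_same_taxon_tips(tree, aln)
        assert len(out.leaf_nodes()) <= 5


class TestRemoveSpuriousTips:
    def test_equal_branches_unchanged(self):
        tree = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        out = remove_spurious_tips(tree, absolute_cutoff=1.5, relative_factor=10)
        assert len(out.leaf_nodes()) == 4

    def test_extreme_tip_removed(self):
        tree = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:5.0):0.1);")
        out = remove_spurious_tips(tree, absolute_cutoff=1.5, relative_factor=10)
        assert sorted(l.taxon.label for l in out.leaf_node_iter()) == ["A", "B", "C"]

    def test_small_trees_untouched(self):
        tree = parse_newick("(A:0.1,B:99.0,C:0.1);")
        out = remove_spurious_tips(tree)
        assert len(out.leaf_nodes()) == 3

    def test_planted_outlier_recall_and_precision(self, pyrng):
        """20x-median planted tips: full recall, zero false removals."""
        removed_ok = 0
        for rep in range(200):
            base = [pyrng.uniform(0.05, 0.15) for _ in range(7)]
            outlier_idx = pyrng.randrange(8)
            lengths = base[:outlier_idx] + [np.median(base) * 20] + base[outlier_idx:]
            labels = [f"t{i}" for i in range(8)]
            nwk = f"({labels[0]}:{lengths[0]},{labels[1]}:{lengths[1]})"
            for lab, ln in zip(labels[2:], lengths[2:]):
                nwk = f"({nwk}:0.05,{lab}:{ln})"
            tree = parse_newick(nwk + ";")
            out = remove_spurious_tips(tree, absolute_cutoff=0.0,
                                       relative_factor=10)
            kept = {l.taxon.label for l in out.leaf_node_iter()}
            assert kept == set(labels) - {labels[outlier_idx]}
            removed_ok += 1
        assert removed_ok == 200


class TestCutDeepParalogs:
    def test_no_long_branch_returns_input(self):
        # unrooted internal edge = 0.1 + 0.1 = 0.2 after derooting
        tree = parse_newick("((A@1:0.1,B@1:0.1):0.1,(C@1:0.1,D@1:0.1):0.1);")
        out = cut_deep_paralogs(tree, branch_cutoff=0.25, min_subtree_taxa=2)
        assert len(out) == 1
        assert len(out[0].leaf_nodes()) == 4

    def _split_tree(self, n_left, n_right, length):
        left = ",".join(f"L{i}@1:0.01" for i in range(n_left))
        right = ",".join(f"R{i}@1:0.01" for i in range(n_right))
        return parse_newick(f"(({left}):{length},({right}):0.01);")

    def test_long_branch_splits_tree(self):
        tree = self._split_tree(22, 21, 0.30)
        out = cut_deep_paralogs(tree, 0.25, 20)
        assert len(out) == 2
        sizes = sorted(len(t.leaf_nodes()) for t in out)
        assert sizes == [21, 22]

    def test_small_component_discarded(self):
        tree = self._split_tree(22, 5, 0.30)
        out = cut_deep_paralogs(tree, 0.25, 20)
        assert len(out) == 1
        assert len(out[0].leaf_nodes()) == 22

    def test_boundary_is_strict(self):
        # derooting merges the basal edges: 0.24 + 0.01 = 0.25, not > cutoff
        tree = self._split_tree(22, 21, 0.24)
        out = cut_deep_paralogs(tree, 0.25, 20)
        assert len(out) == 1

    def test_outputs_have_no_long_internal_branch(self):
        nwk = ("(((a1@1:.01,a2@1:.01,a3@1:.01):0.3,(b1@1:.01,b2@1:.01,"
               "b3@1:.01):0.3):0.01,(c1@1:.01,c2@1:.01,c3@1:.01):0.01);")
        tree = parse_newick(nwk)
        out = cut_deep_paralogs(tree, 0.25, 2)
        for sub in out:
            for nd in sub.preorder_node_iter():
                if nd.parent_node is not None and not nd.is_leaf():
                    assert (nd.edge.length or 0.0) <= 0.25

    def test_components_partition_retained_tips(self):
        tree = self._split_tree(10, 12, 0.4)
        out = cut_deep_paralogs(tree, 0.25, 2)
        all_tips = sorted(
            l.taxon.label for t in out for l in t.leaf_node_iter()
        )
        assert len(all_tips) == len(set(all_tips)) == 22
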