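"""Homolog cluster and tree curation.

The cleaning steps mirror standard phylotranscriptomic practice: taxon
occupancy filtering of clusters, trimming of mostly-missing alignment
columns, masking of redundant same-taxon tips (isoforms/assembly
artifacts), removal of spurious long terminal branches, and cutting of
deep paralogs on long internal branches.

Ordering fixed by this package: trim -> (tree building elsewhere) ->
mask -> remove spurious -> cut deep paralogs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy
import numpy as np

from ._trees import clone, leaf_taxa, taxon_of
from .alignment import Alignment

__all__ = [
    "filter_cluster_occupancy",
    "trim_columns",
    "mask_same_taxon_tips",
    "remove_spurious_tips",
    "cut_deep_paralogs",
    "CurationLogEntry",
]


@dataclass
class CurationLogEntry:
    cluster_id: str
    tips_in: int
    tips_masked: int = 0
    tips_removed_long: int = 0
    subtrees_out: int = 0


def filter_cluster_occupancy(labels: Iterable[str], min_taxa: int) -> bool:
    """Keep a cluster iff it has at least ``min_taxa`` distinct taxa."""
    return len({taxon_of(l) for l in labels}) >= min_taxa


def trim_columns(alignment: Alignment, max_missing_fraction: float) -> Alignment:
    """Remove columns whose missing fraction strictly exceeds the threshold."""
    if alignment.n_rows == 0 or alignment.n_cols == 0:
        return alignment
    frac = alignment.missing_mask().mean(axis=0)
    keep = np.flatnonzero(frac <= max_missing_fraction)
    return alignment.take_columns(keep)


def _prune_leaf(tree: dendropy.Tree, leaf) -> None:
    # the taxon namespace is shared with the input tree; leave it untouched
    parent = leaf.parent_node
    parent.remove_child(leaf)
    tree.suppress_unifurcations()


def mask_same_taxon_tips(
    tree: dendropy.Tree,
    alignment: Optional[Alignment] = None,
) -> dendropy.Tree:
    """Collapse mono/paraphyletic same-taxon tips to the best single tip.

    Two same-taxon tips are redundant when the path between them passes at
    most one clade containing other taxa.  Of each redundant pair, the tip
    with more unambiguous characters in ``alignment`` is kept (ties: the
    lexicographically smaller seqid).  Repeats until fixpoint, so whole
    monophyletic or paraphyletic same-taxon groups shrink to one tip.
    """
    was_rooted = tree.is_rooted
    tree = clone(tree)
    tree.is_rooted = True  # mrca() semantics are seed-rooted either way
    if alignment is not None:
        counts = alignment.unambiguous_counts()
        for lf in tree.leaf_node_iter():
            if lf.taxon.label not in counts:
                raise KeyError(f"tip {lf.taxon.label!r} missing from alignment")
    else:
        counts = {}

    def better(a: str, b: str) -> str:
        ca, cb = counts.get(a, 0), counts.get(b, 0)
        if ca != cb:
            return a if ca > cb else b
        return min(a, b)

    def path_side_clades(la, lb) -> int:
        """Number of off-path subtrees containing non-focal taxa."""
        mrca = dendropy.Tree.mrca(tree, taxa=[la.taxon, lb.taxon])
        taxon = taxon_of(la.taxon.label)
        path_nodes = set()
        for leaf in (la, lb):
            nd = leaf
            while nd is not mrca:
                path_nodes.add(id(nd))
                nd = nd.parent_node
        path_nodes.add(id(mrca))
        off_path: dict[int, object] = {}
        for leaf in (la, lb):
            nd = leaf
            while nd is not mrca:
                parent = nd.parent_node
                for sib in parent.child_nodes():
                    if id(sib) not in path_nodes:
                        off_path[id(sib)] = sib
                nd = parent
        # subtrees hanging off the mrca itself, outside both path arms
        for sib in mrca.child_nodes():
            if id(sib) not in path_nodes:
                off_path[id(sib)] = sib
        n_other = 0
        for sib in off_path.values():
            if any(taxon_of(l.taxon.label) != taxon for l in sib.leaf_iter()):
                n_other += 1
        return n_other

    changed = True
    while changed:
        changed = False
        by_taxon: dict[str, list] = {}
        for lf in tree.leaf_node_iter():
            by_taxon.setdefault(taxon_of(lf.taxon.label), []).append(lf)
        for taxon, leaves in by_taxon.items():
            if len(leaves) < 2:
                continue
            done = False
            for i in range(len(leaves)):
                for j in range(i + 1, len(leaves)):
                    la, lb = leaves[i], leaves[j]
                    if path_side_clades(la, lb) <= 1:
                        keep = better(la.taxon.label, lb.taxon.label)
                        drop = lb if keep == la.taxon.label else la
                        _prune_leaf(tree, drop)
                        changed = True
                        done = True
                        break
                if done:
                    break
            if done:
                break
    tree.is_rooted = was_rooted
    return tree


def remove_spurious_tips(
    tree: dendropy.Tree,
    absolute_cutoff: float = 1.5,
    relative_factor: float = 10.0,
) -> dendropy.Tree:
    """One-pass removal of over-long terminal branches.

    A tip is spurious when its terminal branch exceeds
    ``max(absolute_cutoff, relative_factor * median terminal length)``.
    Trees with fewer than 4 tips are returned unchanged.
    """
    tree = clone(tree)
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 4:
        return tree
    lengths = np.array([lf.edge.length or 0.0 for lf in leaves])
    cutoff = max(absolute_cutoff, relative_factor * float(np.median(lengths)))
    for lf, ln in zip(leaves, lengths):
        if ln > cutoff:
            _prune_leaf(tree, lf)
    return tree


def cut_deep_paralogs(
    tree: dendropy.Tree,
    branch_cutoff: float = 0.25,
    min_subtree_taxa: int = 20,
) -> list[dendropy.Tree]:
    """Cut long internal branches; keep components with enough taxa.

    Works on the unrooted tree: every internal branch (single edge, not a
    path) longer than ``branch_cutoff`` is cut, and each resulting
    connected component with at least ``min_subtree_taxa`` distinct taxa is
    returned as an independent homolog tree.
    """
    work = clone(tree)
    work.deroot()  # basal bifurcation would split one unrooted edge in two

    components: list[dendropy.Node] = []

    def harvest(root_node) -> None:
        """Detach long internal edges below root_node, deepest first."""
        long_edges = [
            nd for nd in root_node.preorder_iter()
            if nd is not root_node and not nd.is_leaf()
            and (nd.edge.length or 0.0) > branch_cutoff
        ]
        # deepest-first so nested cuts detach cleanly
        long_edges.sort(key=lambda nd: -sum(1 for _ in nd.ancestor_iter()))
        for nd in long_edges:
            nd.parent_node.remove_child(nd)
            components.append(nd)
        components.append(root_node)

    harvest(work.seed_node)

    out = []
    for comp in components:
        # drop internal nodes emptied by the detachments
        while True:
            hollow = [
                nd for nd in comp.preorder_iter()
                if nd.taxon is None and not nd.child_nodes() and nd is not comp
            ]
            if not hollow:
                break
            for nd in hollow:
                nd.parent_node.remove_child(nd)
        if comp.taxon is None and not comp.child_nodes():
            continue
        labels = [lf.taxon.label for lf in comp.leaf_iter()]
        if len({taxon_of(l) for l in labels}) < min_subtree_taxa:
            continue
        tns = dendropy.TaxonNamespace()
        sub = dendropy.Tree(taxon_namespace=tns)
        comp.parent_node = None
        comp.edge.length = None
        sub.seed_node = comp
        sub.suppress_unifurcations()
        for lf in sub.leaf_node_iter():
            lf.taxon = dendropy.Taxon(label=lf.taxon.label)
            tns.add_taxon(lf.taxon)
        sub.is_rooted = False
        out.append(sub)
    return out
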