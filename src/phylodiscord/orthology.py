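"""Monophyletic-outgroup (MO) orthology inference.

Homolog trees are accepted only when the outgroup taxa present are
single-copy and monophyletic (in the unrooted sense); the tree is then
rooted on the outgroup edge and traversed from root to tips, deleting the
daughter with fewer taxa at every duplication node (daughters sharing at
least one taxon), until each taxon is represented by one sequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy

from ._trees import clone, leaf_labels, taxon_of
from .alignment import Alignment

__all__ = [
    "RejectReason",
    "MORejection",
    "OrthologGroup",
    "root_by_outgroups",
    "prune_mo",
    "filter_orthologs",
]


class RejectReason(enum.Enum):
    NO_OUTGROUP = "no outgroup tips present"
    OUTGROUP_DUPLICATED = "an outgroup taxon is not single-copy"
    OUTGROUP_NOT_MONOPHYLETIC = "outgroup tips are not monophyletic"


@dataclass
class MORejection(Exception):
    reason: RejectReason

    def __str__(self):
        return self.reason.value


@dataclass
class OrthologGroup:
    tree: dendropy.Tree
    members: list[tuple[str, str]]          # (taxon, seqid)
    source_id: Optional[str] = None
    n_pruning_steps: int = 0

    @property
    def taxa(self) -> set[str]:
        return {t for t, _ in self.members}


def root_by_outgroups(
    homolog_tree: dendropy.Tree,
    outgroup_taxa: Iterable[str],
) -> dendropy.Tree:
    """Root an unrooted homolog tree on its (single-copy, monophyletic) outgroups.

    Monophyly is evaluated on the outgroup taxa actually present: there
    must be an edge separating exactly the outgroup tips from everything
    else.  Raises :class:`MORejection` otherwise.
    """
    og = set(outgroup_taxa)
    if not og:
        raise ValueError("outgroup taxon set is empty")
    tree = clone(tree_unrooted(homolog_tree))
    og_tips = [lf for lf in tree.leaf_node_iter() if taxon_of(lf.taxon.label) in og]
    if not og_tips:
        raise MORejection(RejectReason.NO_OUTGROUP)
    seen: set[str] = set()
    for lf in og_tips:
        t = taxon_of(lf.taxon.label)
        if t in seen:
            raise MORejection(RejectReason.OUTGROUP_DUPLICATED)
        seen.add(t)
    og_labels = frozenset(lf.taxon.label for lf in og_tips)
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if og_labels == all_labels:
        raise MORejection(RejectReason.NO_OUTGROUP)  # nothing ingroup to keep

    if len(og_tips) == 1:
        attach = og_tips[0]
    else:
        attach = None
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if side == og_labels or side == all_labels - og_labels:
                attach = nd
                break
        if attach is None:
            raise MORejection(RejectReason.OUTGROUP_NOT_MONOPHYLETIC)
    edge = attach.edge
    ln = edge.length or 0.0
    tree.reroot_at_edge(edge, length1=ln / 2.0, length2=ln / 2.0)
    tree.is_rooted = True
    tree.suppress_unifurcations()
    return tree


def tree_unrooted(tree: dendropy.Tree) -> dendropy.Tree:
    t = clone(tree)
    t.is_rooted = False
    return t


def prune_mo(
    rooted_tree: dendropy.Tree,
    alignment: Optional[Alignment] = None,
    source_id: Optional[str] = None,
) -> OrthologGroup:
    """Prune duplications root-to-tip, keeping the taxon-richer side.

    At each node whose two daughter clades share >= 1 taxon, the daughter
    with fewer distinct taxa is deleted (ties: fewer tips, then fewer
    unambiguous characters, then lexicographically smaller seqid list) and
    the traversal continues, until no taxon is represented twice.
    """
    tree = clone(rooted_tree)
    counts = alignment.unambiguous_counts() if alignment is not None else {}
    steps = 0

    def clade_stats(nd):
        labels = [lf.taxon.label for lf in nd.leaf_iter()]
        taxa = {taxon_of(l) for l in labels}
        chars = sum(counts.get(l, 0) for l in labels)
        seqids = ",".join(sorted(l.split("@", 1)[-1] for l in labels))
        return taxa, len(labels), chars, seqids

    def process(nd):
        nonlocal steps
        while True:
            kids = nd.child_nodes()
            if len(kids) < 2:
                break
            # polytomies: treat pairwise; binary in practice
            dup_pair = None
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    ta, *_ = clade_stats(kids[i])
                    tb, *_ = clade_stats(kids[j])
                    if ta & tb:
                        dup_pair = (kids[i], kids[j])
                        break
                if dup_pair:
                    break
            if dup_pair is None:
                break
            a, b = dup_pair
            sa, sb = clade_stats(a), clade_stats(b)
            # keep the side with more taxa; ties by tips, chars, seqids
            keep_a = (len(sa[0]), sa[1], sa[2], sa[3]) > (len(sb[0]), sb[1], sb[2], sb[3])
            victim = b if keep_a else a
            nd.remove_child(victim)
            steps += 1
            if len(nd.child_nodes()) == 1:
                only = nd.child_nodes()[0]
                parent = nd.parent_node
                only.edge.length = (only.edge.length or 0.0) + (nd.edge.length or 0.0)
                if parent is None:
                    tree.seed_node = only
                    only.parent_node = None
                    nd = only
                else:
                    parent.remove_child(nd)
                    parent.add_child(only)
                    nd = only
                if nd.is_leaf():
                    break
        for c in list(nd.child_nodes()):
            if not c.is_leaf():
                process(c)

    process(tree.seed_node)
    members = sorted(
        (taxon_of(l), l.split("@", 1)[-1]) for l in leaf_labels(tree)
    )
    taxa = [t for t, _ in members]
    assert len(set(taxa)) == len(taxa), "MO output contains a duplicated taxon"
    return OrthologGroup(tree=tree, members=members, source_id=source_id, n_pruning_steps=steps)


def filter_orthologs(groups: Sequence[OrthologGroup], min_taxa: int) -> list[OrthologGroup]:
    """Keep groups with at least ``min_taxa`` distinct taxa."""
    return [g for g in groups if len(g.taxa) >= min_taxa]
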