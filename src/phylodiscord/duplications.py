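"""Gene-duplication mapping onto the species tree.

Rooted ingroup clades are extracted from curated homolog trees (rooted by
an adjacent outgroup, filtered by average bootstrap support and taxon
count); each clade node whose two daughters share two or more taxa is a
duplication event, mapped to the MRCA of the node's taxon set on the
species tree.  Per-branch percentages are reported against the number of
extracted clades informative for that branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from ._trees import clone, leaf_taxa, node_support, taxon_of

__all__ = [
    "DuplicationEvent",
    "extract_rooted_clades",
    "map_duplications",
    "duplication_percentages",
]


@dataclass
class DuplicationEvent:
    clade_id: str
    species_branch: frozenset     # descendant taxa of the mapped species branch
    n_overlap: int                # taxa shared by the two daughter clades

    def __post_init__(self):
        assert self.n_overlap >= 2


class UnsupportedTreeError(ValueError):
    """Homolog tree carries no bootstrap labels; run bootstrap first."""


def _mean_internal_support(node) -> Optional[float]:
    vals = []
    for nd in node.preorder_iter():
        if nd.is_leaf() or nd is node:
            continue
        sup = node_support(nd)
        if sup is not None:
            vals.append(sup)
    root_sup = node_support(node)
    if root_sup is not None:
        vals.append(root_sup)
    return float(np.mean(vals)) if vals else None


def extract_rooted_clades(
    homolog_tree: dendropy.Tree,
    outgroup_taxa: Iterable[str],
    min_avg_support: float = 50.0,
    min_taxa: int = 15,
    clade_prefix: str = "clade",
) -> list[dendropy.Tree]:
    """Maximal ingroup-only clades, rooted by adjacency to an outgroup.

    The homolog tree is rooted at an outgroup tip; every maximal clade
    containing no outgroup taxon, with mean internal bootstrap support
    >= ``min_avg_support`` and >= ``min_taxa`` distinct taxa, is returned
    as an independent rooted tree.
    """
    og = set(outgroup_taxa)
    if not any(node_support(nd) is not None
               for nd in homolog_tree.preorder_node_iter() if not nd.is_leaf()):
        raise UnsupportedTreeError(
            "homolog tree has no bootstrap labels; run bootstrap_support first"
        )
    tree = clone(homolog_tree)
    og_tips = [lf for lf in tree.leaf_node_iter() if taxon_of(lf.taxon.label) in og]
    if not og_tips:
        return []
    tree.reroot_at_edge(og_tips[0].edge)
    tree.is_rooted = True

    out = []
    counter = [0]

    def visit(nd):
        taxa = {taxon_of(l.taxon.label) for l in nd.leaf_iter()}
        if not (taxa & og):
            # maximal ingroup clade
            if len(taxa) >= min_taxa:
                avg = _mean_internal_support(nd)
                if avg is not None and avg >= min_avg_support:
                    counter[0] += 1
                    sub = _clade_to_tree(nd)
                    sub.label = f"{clade_prefix}{counter[0]}"
                    out.append(sub)
            return
        for c in nd.child_nodes():
            visit(c)

    visit(tree.seed_node)
    return out


def _copy_node(nd, tns) -> dendropy.Node:
    new = dendropy.Node()
    new.edge.length = nd.edge.length
    new.support = getattr(nd, "support", None)
    if nd.is_leaf():
        new.taxon = dendropy.Taxon(label=nd.taxon.label)
        tns.add_taxon(new.taxon)
    else:
        for c in nd.child_nodes():
            new.add_child(_copy_node(c, tns))
    return new


def _clade_to_tree(node) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    sub = dendropy.Tree(taxon_namespace=tns)
    sub.seed_node = _copy_node(node, tns)
    sub.seed_node.edge.length = None
    sub.is_rooted = True
    return sub


def map_duplications(
    rooted_clade: dendropy.Tree,
    species_tree: dendropy.Tree,
    min_overlap: int = 2,
) -> list[DuplicationEvent]:
    """Map duplication nodes (daughter taxon overlap >= 2) to species MRCAs."""
    sp_taxa = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    clade_taxa = leaf_taxa(rooted_clade.seed_node)
    missing = clade_taxa - sp_taxa
    if missing:
        raise ValueError(f"clade taxa absent from species tree: {sorted(missing)}")
    label = rooted_clade.label or "clade"
    events = []
    for nd in rooted_clade.preorder_node_iter():
        kids = nd.child_nodes()
        if len(kids) != 2:
            continue
        ta = leaf_taxa(kids[0])
        tb = leaf_taxa(kids[1])
        overlap = ta & tb
        if len(overlap) >= min_overlap:
            node_taxa = ta | tb
            mrca = species_tree.mrca(
                taxa=[lf.taxon for lf in species_tree.leaf_node_iter()
                      if lf.taxon.label in node_taxa]
            )
            branch = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
            events.append(DuplicationEvent(
                clade_id=label, species_branch=branch, n_overlap=len(overlap),
            ))
    return events


def duplication_percentages(
    events: Sequence[DuplicationEvent],
    clades: Sequence[dendropy.Tree],
    species_tree: dendropy.Tree,
) -> dict[frozenset, tuple[int, Optional[float]]]:
    """Per-branch duplication counts and percentages.

    Percentage = events mapped to the branch / number of extracted clades
    whose taxon set contains >= 2 descendants of the branch, x 100.
    Branches informative for no clade get percentage None.
    """
    clade_taxa = [leaf_taxa(c.seed_node) for c in clades]
    out: dict[frozenset, tuple[int, Optional[float]]] = {}
    for nd in species_tree.preorder_node_iter():
        if nd.is_leaf() and nd.parent_node is not None:
            branch = frozenset([nd.taxon.label])
        else:
            branch = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        count = sum(1 for ev in events if ev.species_branch == branch)
        denom = sum(1 for ct in clade_taxa if len(ct & branch) >= 2)
        pct = (100.0 * count / denom) if denom else None
        out[branch] = (count, pct)
    return out
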