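"""Shared tree helpers built on dendropy.

Conventions used across the package:

* gene/homolog tree tips are labelled ``taxon@seqid``;
* bootstrap support is stored as the internal-node *label* in newick
  (the convention RAxML-style pipelines use) and mirrored onto
  ``node.support`` as an integer in [0, 100] when parsed;
* bipartitions are represented as frozensets of taxon labels (one side),
  normalised against an explicit reference taxon set.
"""

from __future__ import annotations

from typing import Iterable, Optional

import dendropy

__all__ = [
    "taxon_of",
    "seqid_of",
    "parse_newick",
    "to_newick",
    "leaf_labels",
    "leaf_taxa",
    "clone",
    "node_support",
    "internal_bipartitions",
    "restrict",
    "is_informative",
    "incompatible",
]


def taxon_of(label: str) -> str:
    """Taxon part of a ``taxon@seqid`` tip label (label itself if no '@')."""
    return label.split("@", 1)[0]


def seqid_of(label: str) -> str:
    return label.split("@", 1)[1] if "@" in label else ""


def parse_newick(newick: str, rooted: bool = False) -> dendropy.Tree:
    """Parse a newick string; internal node labels are read as support values."""
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        rooting="force-rooted" if rooted else "force-unrooted",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    annotate_support(tree)
    return tree


def annotate_support(tree: dendropy.Tree) -> None:
    """Mirror internal-node newick labels onto integer ``node.support``."""
    for nd in tree.preorder_node_iter():
        sup = None
        if not nd.is_leaf() and nd.label is not None:
            try:
                sup = int(round(float(nd.label)))
            except ValueError:
                sup = None
        nd.support = sup


def to_newick(tree: dendropy.Tree) -> str:
    """Serialize with supports as internal node labels."""
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            sup = getattr(nd, "support", None)
            nd.label = str(int(sup)) if sup is not None else None
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def leaf_labels(tree_or_node) -> list[str]:
    if isinstance(tree_or_node, dendropy.Tree):
        return [lf.taxon.label for lf in tree_or_node.leaf_node_iter()]
    return [lf.taxon.label for lf in tree_or_node.leaf_iter()]


def leaf_taxa(tree_or_node) -> set[str]:
    return {taxon_of(l) for l in leaf_labels(tree_or_node)}


def clone(tree: dendropy.Tree) -> dendropy.Tree:
    out = tree.clone(depth=1)
    for nd, nd0 in zip(out.preorder_node_iter(), tree.preorder_node_iter()):
        nd.support = getattr(nd0, "support", None)
    return out


def node_support(node, default: Optional[int] = None) -> Optional[int]:
    sup = getattr(node, "support", None)
    if sup is None and node.label is not None:
        try:
            sup = int(round(float(node.label)))
        except ValueError:
            sup = None
    return default if sup is None else sup


def internal_bipartitions(
    tree: dendropy.Tree,
    with_support: bool = False,
):
    """Yield unrooted internal bipartitions as (side_frozenset, support).

    ``side`` is the leaf-label set below each internal edge; the full taxon
    set of the tree defines the complement.  The trivial all-taxa side and
    single-leaf sides are skipped.  For a bifurcating root, the two root
    edges describe the same unrooted bipartition; it is yielded once.
    """
    all_leaves = frozenset(leaf_labels(tree))
    seen: set[frozenset] = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        comp = all_leaves - side
        if len(side) < 2 or len(comp) < 2:
            continue
        key = min(side, comp, key=sorted)
        if key in seen:
            continue
        seen.add(key)
        if with_support:
            yield side, node_support(nd)
        else:
            yield side


def restrict(side: frozenset, full: frozenset, common: frozenset):
    """Restrict a bipartition (side vs full-side) to ``common`` taxa.

    Returns (a, b) or None if uninformative on the common set.
    """
    a = frozenset(side & common)
    b = frozenset((full - side) & common)
    if len(a) < 2 or len(b) < 2:
        return None
    return a, b


def is_informative(pair) -> bool:
    return pair is not None


def same_split(p1, p2) -> bool:
    """Two restricted bipartitions over the same taxon set are equal."""
    return p1[0] == p2[0] or p1[0] == p2[1]


def incompatible(p1, p2) -> bool:
    """Standard four-intersection incompatibility on a shared taxon set."""
    a1, b1 = p1
    a2, b2 = p2
    return bool(a1 & a2) and bool(a1 & b2) and bool(b1 & a2) and bool(b1 & b2)
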