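"""Per-branch gene-tree/species-tree bipartition concordance.

For every internal branch of the species tree, each gene tree is scored as
concordant, conflicting (with the most frequent conflicting bipartition
tracked as the top alternative), or uninformative, after restricting the
branch's bipartition to the gene tree's taxon set and applying a bootstrap
support filter — the pie-chart accounting used around species trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy

from ._trees import (
    incompatible,
    internal_bipartitions,
    leaf_labels,
    restrict,
    taxon_of,
)

__all__ = ["BranchConcordance", "ConcordanceSummary", "map_bipartitions",
           "conflict_profile_by_removal"]


@dataclass
class BranchConcordance:
    """Counts for one species-tree internal branch."""

    branch: frozenset                    # taxa on the child side
    n_concordant: int = 0
    n_top_alternative: int = 0
    n_other_conflict: int = 0
    n_uninformative: int = 0
    top_alternative: Optional[frozenset] = None  # one side of the modal conflict

    @property
    def total(self) -> int:
        return (self.n_concordant + self.n_top_alternative
                + self.n_other_conflict + self.n_uninformative)

    @property
    def n_conflict(self) -> int:
        return self.n_top_alternative + self.n_other_conflict


@dataclass
class ConcordanceSummary:
    branches: list[BranchConcordance]
    n_gene_trees: int

    def by_branch(self) -> dict[frozenset, BranchConcordance]:
        return {b.branch: b for b in self.branches}

    @property
    def total_conflict(self) -> int:
        return sum(b.n_conflict for b in self.branches)


def _gene_bipartitions(gene_tree, min_support):
    """(side, complement-on-own-taxa) pairs passing the support filter.

    Unlabelled internal branches are treated as fully supported, so plain
    topologies (e.g. simulated gene trees) are usable without bootstrap.
    """
    full = frozenset(leaf_labels(gene_tree))
    out = []
    for side, sup in internal_bipartitions(gene_tree, with_support=True):
        if sup is not None and sup < min_support:
            continue
        out.append((side, full - side))
    return full, out


def map_bipartitions(
    species_tree: dendropy.Tree,
    gene_trees: Sequence[dendropy.Tree],
    min_support: int = 50,
) -> ConcordanceSummary:
    """PhyParts-style concordance/conflict counts per species-tree branch.

    Gene-tree tips may be a taxon subset; tips named ``taxon@seqid`` are
    matched by taxon.  A gene tree is concordant at a branch if it has a
    supported bipartition equal to the branch's restriction to the shared
    taxa; conflicting if a supported, informative bipartition is
    incompatible with the restriction; otherwise uninformative.
    """
    sp_full = frozenset(leaf_labels(species_tree))
    branches = [
        BranchConcordance(branch=side) for side in internal_bipartitions(species_tree)
    ]
    # pre-extract gene tree bipartitions once, keyed by taxon
    prepared = []
    for gt in gene_trees:
        full, bips = _gene_bipartitions(gt, min_support)
        by_taxon_full = frozenset(taxon_of(l) for l in full)
        bips_taxa = [
            (frozenset(taxon_of(l) for l in a), frozenset(taxon_of(l) for l in b))
            for a, b in bips
        ]
        prepared.append((by_taxon_full, bips_taxa))

    for bc in branches:
        alt_tally: dict[frozenset, int] = {}
        conflict_votes = []
        for gt_taxa, gt_bips in prepared:
            common = sp_full & gt_taxa
            target = restrict(bc.branch, sp_full, common)
            if target is None or len(common) < 4:
                bc.n_uninformative += 1
                continue
            concordant = False
            conflicts = []
            for a, b in gt_bips:
                ra, rb = frozenset(a & common), frozenset(b & common)
                if len(ra) < 2 or len(rb) < 2:
                    continue
                if ra == target[0] or ra == target[1]:
                    concordant = True
                    break
                if incompatible((ra, rb), target):
                    conflicts.append((ra, rb))
            if concordant:
                bc.n_concordant += 1
            elif conflicts:
                # one vote per tree: its smallest conflicting side (determinism)
                vote = min(
                    (min(ra, rb, key=sorted) for ra, rb in conflicts), key=sorted
                )
                conflict_votes.append(vote)
                alt_tally[vote] = alt_tally.get(vote, 0) + 1
            else:
                bc.n_uninformative += 1
        if alt_tally:
            top = max(alt_tally, key=lambda k: (alt_tally[k], sorted(k)))
            bc.top_alternative = top
            bc.n_top_alternative = alt_tally[top]
            bc.n_other_conflict = len(conflict_votes) - alt_tally[top]
    return ConcordanceSummary(branches=branches, n_gene_trees=len(gene_trees))


def _prune_taxon(tree: dendropy.Tree, taxon: str) -> dendropy.Tree:
    t = tree.clone(depth=1)
    for nd, nd0 in zip(t.preorder_node_iter(), tree.preorder_node_iter()):
        nd.support = getattr(nd0, "support", None)
    drop = [lf for lf in t.leaf_node_iter() if taxon_of(lf.taxon.label) == taxon]
    for lf in drop:
        lf.parent_node.remove_child(lf)
    t.suppress_unifurcations()
    return t


def conflict_profile_by_removal(
    species_tree: dendropy.Tree,
    gene_trees: Sequence[dendropy.Tree],
    min_support: int = 50,
) -> list[tuple[str, int]]:
    """Rank taxa by how much total conflict their removal eliminates.

    Returns (taxon, conflict_reduction) sorted by reduction, largest
    first (ties alphabetical).  Reduction is baseline total conflicting
    count minus the total after pruning the taxon everywhere.
    """
    taxa = sorted({taxon_of(l) for l in leaf_labels(species_tree)})
    if len(taxa) < 5:
        raise ValueError("need at least 5 taxa to profile removals")
    baseline = map_bipartitions(species_tree, gene_trees, min_support).total_conflict
    rows = []
    for x in taxa:
        sp = _prune_taxon(species_tree, x)
        gts = [_prune_taxon(gt, x) for gt in gene_trees]
        score = map_bipartitions(sp, gts, min_support).total_conflict
        rows.append((x, baseline - score))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows
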