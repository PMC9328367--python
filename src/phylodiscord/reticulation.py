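"""Triplet-based introgression tests with inheritance-probability estimates.

For an ordered triplet (H, P1, P2) the rooted-triplet topologies of the
gene trees are tallied as n1 (species-tree-concordant), n2 (H grouped with
P2, the candidate introgression signal) and n3 (the remaining topology).
Under ILS alone the two minor topologies are equifrequent, so the
asymmetry test is an exact two-sided binomial on (n2, n3).

The inheritance probability is estimated as

    gamma_hat = (n2 - n3) / (n1 + n2 - 2 n3)

which follows from the network-MSC expectations p1 - p3 = (1-g)(1-e^-tA)
and p2 - p3 = g (1-e^-tB): the estimator is exactly unbiased when the two
parental internal branches are equal (tA = tB) and biased otherwise.  All
triplets are tested in all three hybrid-role directions; family-wise
significance uses a Bonferroni correction over the tests with
gamma_hat_raw strictly inside (0, 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import binomtest

from ._trees import leaf_labels, taxon_of

__all__ = ["TripletCounts", "GammaEstimate", "count_triplets",
           "estimate_gamma", "scan_all_triplets", "induced_triplet"]


@dataclass
class TripletCounts:
    hybrid: str
    parent1: str
    parent2: str
    n1: int   # species-tree-concordant topology
    n2: int   # ((H,P2),P1)-style candidate introgression topology
    n3: int   # remaining topology
    species_topology: tuple  # cherry pair of the species-tree triplet

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3


@dataclass
class GammaEstimate:
    counts: TripletCounts
    gamma_raw: Optional[float]
    gamma: Optional[float]      # clipped to [0, 1]; None when undefined
    p_value: float
    significant: bool = False
    equal_branch_assumption: str = (
        "unbiased only if the two parental internal branches are equal"
    )


def induced_triplet(gene_tree: dendropy.Tree, taxa: Sequence[str]) -> Optional[tuple]:
    """Cherry pair of the rooted triplet induced on three taxa, or None.

    None when a taxon is missing from the tree, has several tips, or the
    triplet is unresolved.  Tips named ``taxon@seqid`` match by taxon.
    """
    return _cherry_from_depths(pair_mrca_depths(gene_tree), tuple(taxa))


def pair_mrca_depths(tree: dendropy.Tree) -> dict[tuple[str, str], int]:
    """MRCA depth (root = 0) for every single-copy taxon pair, in one sweep.

    Taxa with several tips are excluded (single-copy trees expected).
    Keys are sorted (taxon_a, taxon_b) tuples.
    """
    multi: set[str] = set()
    seen: set[str] = set()
    for lf in tree.leaf_node_iter():
        t = taxon_of(lf.taxon.label)
        if t in seen:
            multi.add(t)
        seen.add(t)
    depths: dict[tuple[str, str], int] = {}
    subtree_taxa: dict[int, list[str]] = {}
    node_depth: dict[int, int] = {}
    for nd in tree.preorder_node_iter():
        p = nd.parent_node
        node_depth[id(nd)] = 0 if p is None else node_depth[id(p)] + 1
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            t = taxon_of(nd.taxon.label)
            subtree_taxa[id(nd)] = [] if t in multi else [t]
            continue
        kids = [subtree_taxa.pop(id(c)) for c in nd.child_nodes()]
        d = node_depth[id(nd)]
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                for a in kids[i]:
                    for b in kids[j]:
                        key = (a, b) if a < b else (b, a)
                        depths[key] = d
        subtree_taxa[id(nd)] = [t for kid in kids for t in kid]
    return depths


def _cherry_from_depths(depths, triple) -> Optional[tuple]:
    x, y, z = sorted(triple)
    pairs = [(x, y), (x, z), (y, z)]
    try:
        vals = [depths[p] for p in pairs]
    except KeyError:
        return None
    ranked = sorted(zip(vals, pairs), key=lambda kv: -kv[0])
    if ranked[0][0] == ranked[1][0]:
        return None  # polytomy
    return ranked[0][1]


def count_triplets(
    gene_trees: Sequence[dendropy.Tree],
    triplet: tuple[str, str, str],
    species_tree: dendropy.Tree,
    _depth_maps: Optional[Sequence[dict]] = None,
) -> TripletCounts:
    """Tally rooted-triplet topologies of the gene trees for (H, P1, P2).

    Slot convention: n1 counts the species-tree-concordant topology, n2
    the topology grouping H with P2, and n3 the remaining one.  When H is
    the species-triplet outlier, n1 is the (P1,P2) cherry; otherwise
    (H sister to P1) the slots are literally n1=((H,P1),P2),
    n2=((H,P2),P1), n3=((P1,P2),H).
    """
    h, p1, p2 = triplet
    sp_taxa = {taxon_of(l) for l in leaf_labels(species_tree)}
    for t in triplet:
        if t not in sp_taxa:
            raise ValueError(f"taxon {t!r} not in species tree")
    sp_top = induced_triplet(species_tree, triplet)
    if sp_top is None:
        raise ValueError("species tree does not resolve the triplet")
    key_n2 = tuple(sorted((h, p2)))
    if _depth_maps is None:
        _depth_maps = [pair_mrca_depths(gt) for gt in gene_trees]
    tally = {}
    for dm in _depth_maps:
        top = _cherry_from_depths(dm, triplet)
        if top is not None:
            tally[top] = tally.get(top, 0) + 1
    pairs = [tuple(sorted(p)) for p in itertools.combinations(sorted(triplet), 2)]
    n1 = tally.get(sp_top, 0)
    if key_n2 == sp_top:
        # candidate topology IS the species topology; keep n1 as concordant
        # and n2 as the (H,P2) grouping only when they differ
        n2 = 0
        rest = [p for p in pairs if p != sp_top]
    else:
        n2 = tally.get(key_n2, 0)
        rest = [p for p in pairs if p not in (sp_top, key_n2)]
    n3 = sum(tally.get(p, 0) for p in rest)
    return TripletCounts(h, p1, p2, n1, n2, n3, sp_top)


def estimate_gamma(counts: TripletCounts) -> GammaEstimate:
    """Asymmetry-based inheritance probability and exact binomial test."""
    n1, n2, n3 = counts.n1, counts.n2, counts.n3
    if n1 + n2 + n3 == 0:
        raise ValueError("no informative gene trees for the triplet")
    denom = n1 + n2 - 2 * n3
    if denom <= 0:
        gamma_raw = gamma = None
    else:
        gamma_raw = (n2 - n3) / denom
        gamma = min(1.0, max(0.0, gamma_raw))
    if n2 + n3 == 0:
        p = 1.0
    else:
        p = binomtest(n2, n2 + n3, 0.5, alternative="two-sided").pvalue
    return GammaEstimate(counts=counts, gamma_raw=gamma_raw, gamma=gamma, p_value=p)


def scan_all_triplets(
    gene_trees: Sequence[dendropy.Tree],
    species_tree: dendropy.Tree,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every taxon triple in all three hybrid-role directions.

    Returns a table sorted by p-value with Bonferroni-corrected
    significance; the correction denominator is the number of tests with
    gamma_hat_raw strictly inside (0, 1).
    """
    taxa = sorted({taxon_of(l) for l in leaf_labels(species_tree)})
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    depth_maps = [pair_mrca_depths(gt) for gt in gene_trees]
    sp_depths = pair_mrca_depths(species_tree)
    rows = []
    for triple in itertools.combinations(taxa, 3):
        sp_top = _cherry_from_depths(sp_depths, triple)
        if sp_top is None:
            continue
        for h in triple:
            others = [t for t in triple if t != h]
            if h in sp_top:
                # orient P1 as H's species-tree sister so n1 = ((H,P1),P2)
                p1 = sp_top[0] if sp_top[1] == h else sp_top[1]
                p2 = next(t for t in others if t != p1)
            else:
                p1, p2 = sorted(others)
            counts = count_triplets(
                gene_trees, (h, p1, p2), species_tree, _depth_maps=depth_maps
            )
            if counts.total == 0:
                continue
            est = estimate_gamma(counts)
            rows.append({
                "hybrid": h, "parent1": p1, "parent2": p2,
                "n1": counts.n1, "n2": counts.n2, "n3": counts.n3,
                "gamma_raw": est.gamma_raw, "gamma": est.gamma,
                "p": est.p_value,
            })
    df = pd.DataFrame(rows)
    testable = df["gamma_raw"].apply(
        lambda g: g is not None and 0.0 < g < 1.0
    )
    n_tests = max(int(testable.sum()), 1)
    df["p_bonferroni"] = (df["p"] * n_tests).clip(upper=1.0)
    df["significant"] = testable & (df["p"] * n_tests <= alpha)
    df = df.sort_values(["p", "hybrid", "parent1", "parent2"]).reset_index(drop=True)
    return df
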