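"""Distance-based gene trees: JC69 + neighbor joining + bootstrap.

A self-contained gene-tree stage: pairwise Jukes–Cantor distances with
pairwise deletion, classic neighbor joining (negative branch lengths are
clamped to zero at join time, moving the deficit to the sister branch),
and nonparametric bootstrap support.  Also houses the ortholog-alignment
filters and supermatrix concatenation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from ._trees import internal_bipartitions, taxon_of
from .alignment import Alignment

__all__ = [
    "DistanceMatrix",
    "SaturatedDistanceError",
    "MissingDistanceError",
    "jc_distance",
    "neighbor_joining",
    "bootstrap_support",
    "filter_ortholog_alignment",
    "concatenate",
    "majority_consensus",
]

_AMBIG = frozenset(b"-N?")


class MissingDistanceError(ValueError):
    """A pair of rows shares no unambiguously resolved sites."""


class SaturatedDistanceError(ValueError):
    """NJ input contains saturated (p >= 3/4) or missing distances."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray          # JC distances
    p: np.ndarray          # proportions of differing sites
    saturated: np.ndarray  # boolean mask of p >= 3/4 pairs

    def __post_init__(self):
        assert self.d.shape == (len(self.labels), len(self.labels))


def jc_distance(alignment: Alignment, saturation_ceiling: float = 5.0) -> DistanceMatrix:
    """Pairwise JC69 distances with pairwise deletion.

    For each pair, p is computed over sites where both rows are in
    {A,C,G,T}; d = -(3/4) ln(1 - 4p/3).  Pairs at or beyond p = 3/4 are
    flagged saturated and get d = ``saturation_ceiling``.
    """
    n = alignment.n_rows
    if n < 2:
        raise ValueError("need at least 2 rows")
    good = ~alignment.missing_mask()
    X = alignment.data.view(np.uint8)
    d = np.zeros((n, n))
    p = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            both = good[i] & good[j]
            m = int(both.sum())
            if m == 0:
                raise MissingDistanceError(
                    f"no comparable sites between {alignment.labels[i]!r} "
                    f"and {alignment.labels[j]!r}"
                )
            pij = float((X[i, both] != X[j, both]).sum()) / m
            p[i, j] = p[j, i] = pij
            if pij >= 0.75:
                sat[i, j] = sat[j, i] = True
                d[i, j] = d[j, i] = saturation_ceiling
            else:
                dij = -0.75 * math.log(1.0 - 4.0 * pij / 3.0)
                d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(alignment.labels), d, p, sat)


def neighbor_joining(dist: DistanceMatrix, forbid_saturated: bool = True) -> dendropy.Tree:
    """Classic NJ agglomeration; returns an unrooted dendropy tree.

    Negative branch lengths arising at a join are clamped to 0 with the
    deficit moved to the sister branch, the standard correction.
    """
    if forbid_saturated and dist.saturated.any():
        pairs = [
            (dist.labels[i], dist.labels[j])
            for i, j in zip(*np.nonzero(np.triu(dist.saturated)))
        ]
        raise SaturatedDistanceError(f"saturated pairs: {pairs}")
    n = len(dist.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    tns = dendropy.TaxonNamespace()
    nodes = []
    for lab in dist.labels:
        nd = dendropy.Node()
        nd.taxon = dendropy.Taxon(label=lab)
        tns.add_taxon(nd.taxon)
        nodes.append(nd)
    D = dist.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # grow D with the new node's distances
        new_idx = D.shape[0]
        newrow = np.zeros(new_idx + 1)
        for k in active:
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new_idx, : new_idx] = newrow[:new_idx]
        D[: new_idx, new_idx] = newrow[:new_idx]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j = active
    root = dendropy.Node()
    if nodes[i].is_leaf() and nodes[j].is_leaf():
        # trivial 2-taxon case (n >= 3 guard means one side is internal)
        nodes[i].edge.length = D[i, j] / 2
        nodes[j].edge.length = D[i, j] / 2
        root.add_child(nodes[i])
        root.add_child(nodes[j])
    else:
        # attach the remaining pair by a single edge: merge into the
        # internal one to get the conventional unrooted (trifurcating) form
        internal = nodes[j] if not nodes[j].is_leaf() else nodes[i]
        other = nodes[i] if internal is nodes[j] else nodes[j]
        other.edge.length = max(D[i, j], 0.0)
        internal.add_child(other)
        root = internal
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    for nd in tree.preorder_node_iter():
        nd.support = None
    return tree


def _nj_from_alignment(alignment: Alignment, saturation_ceiling: float = 5.0) -> dendropy.Tree:
    return neighbor_joining(jc_distance(alignment, saturation_ceiling), forbid_saturated=False)


def bootstrap_support(
    alignment: Alignment,
    n_reps: int = 200,
    seed: int = 0,
    saturation_ceiling: float = 5.0,
) -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap support on internal branches.

    Columns are resampled with replacement ``n_reps`` times; the original
    NJ tree's bipartitions are annotated with their replicate frequency
    x 100, floor-rounded to an integer.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    base = _nj_from_alignment(alignment, saturation_ceiling)
    counts: dict[frozenset, int] = {}
    all_taxa = frozenset(alignment.labels)
    targets = {}
    for nd in base.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(side) < 2 or len(all_taxa - side) < 2:
            continue
        key = min(side, all_taxa - side, key=sorted)
        targets[id(nd)] = key
        counts[key] = 0
    for _ in range(n_reps):
        idx = rng.integers(0, alignment.n_cols, size=alignment.n_cols)
        rep = alignment.take_columns(idx)
        try:
            rtree = _nj_from_alignment(rep, saturation_ceiling)
        except MissingDistanceError:
            continue
        seen = set()
        for side in internal_bipartitions(rtree):
            seen.add(min(side, all_taxa - side, key=sorted))
        for key in counts:
            if key in seen:
                counts[key] += 1
    for nd in base.preorder_node_iter():
        if id(nd) in targets:
            nd.support = int(counts[targets[id(nd)]] * 100 // n_reps)
    return base


def filter_ortholog_alignment(
    alignment: Alignment,
    min_length: int,
    required_taxa: Iterable[str],
) -> bool:
    """Keep iff long enough and covering all required taxa."""
    taxa = {taxon_of(l) for l in alignment.labels}
    return alignment.n_cols >= min_length and taxa >= set(required_taxa)


def concatenate(orthologs: Sequence[Alignment]):
    """Concatenate per-locus alignments into a supermatrix.

    Rows are keyed by taxon; loci missing a taxon contribute a '?' block.
    Returns (supermatrix, occupancy, partitions) where partitions maps
    locus index -> (start, end) half-open 0-based column ranges.
    """
    taxa: list[str] = []
    for aln in orthologs:
        seen = set()
        for lab in aln.labels:
            t = taxon_of(lab)
            if t in seen:
                raise ValueError(f"duplicate taxon {t!r} within one locus")
            seen.add(t)
            if t not in taxa:
                taxa.append(t)
    taxa.sort()
    blocks = []
    partitions: dict[int, tuple[int, int]] = {}
    start = 0
    for li, aln in enumerate(orthologs):
        L = aln.n_cols
        block = np.full((len(taxa), L), b"?", dtype="S1")
        for r, lab in enumerate(aln.labels):
            block[taxa.index(taxon_of(lab))] = aln.data[r]
        blocks.append(block)
        partitions[li] = (start, start + L)
        start += L
    data = np.hstack(blocks) if blocks else np.empty((0, 0), "S1")
    sm = Alignment(taxa, data)
    return sm, sm.occupancy(), partitions


def write_partitions(partitions: dict[int, tuple[int, int]], handle) -> None:
    """RAxML-style partition file (1-based inclusive coordinates)."""
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        for li, (s, e) in sorted(partitions.items()):
            handle.write(f"DNA, locus{li} = {s + 1}-{e}\n")
    finally:
        if close:
            handle.close()


def majority_consensus(trees: Sequence[dendropy.Tree], min_freq: float = 0.5) -> dendropy.Tree:
    """Greedy majority-rule consensus of gene trees (shared taxon namespace)."""
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        tl.append(
            dendropy.Tree.get(
                data=t.as_string(schema="newick"),
                schema="newick",
                taxon_namespace=tns,
                preserve_underscores=True,
            )
        )
    cons = tl.consensus(min_freq=min_freq)
    cons.is_rooted = False
    for nd in cons.preorder_node_iter():
        nd.support = None
    return cons
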