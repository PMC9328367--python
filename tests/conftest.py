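"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import itertools
import random

import dendropy
import numpy as np
import pytest

from phylodiscord._trees import parse_newick
from phylodiscord.alignment import Alignment

NUCS = "ACGT"


# ---------------------------------------------------------------------------
# random data generators (test-local, independent of the package simulator)

def random_alignment(rng: np.random.Generator, n_rows: int, n_cols: int,
                     missing_frac: float = 0.1, prefix: str = "t") -> Alignment:
    chars = np.array(list("ACGT-N?"), dtype="U1")
    probs = [(1 - missing_frac) / 4] * 4 + [missing_frac / 3] * 3
    data = rng.choice(chars, size=(n_rows, n_cols), p=probs)
    labels = [f"{prefix}{i}" for i in range(n_rows)]
    return Alignment.from_pairs((lab, "".join(row)) for lab, row in zip(labels, data))


def random_topology(rng: random.Random, taxa: list[str]) -> dict:
    """Random rooted binary topology as nested tuples of labels."""
    nodes = list(taxa)
    rng.shuffle(nodes)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append((a, b))
    return nodes[0]


def random_additive_matrix(rng: random.Random, taxa: list[str]):
    """(distance matrix, set of non-trivial bipartitions) from a random tree.

    Branch lengths uniform in [0.1, 1.0]; distances are exact path sums, so
    the matrix is additive by construction.
    """
    topo = random_topology(rng, taxa)
    dist = {t: {} for t in taxa}
    bipartitions = set()

    def leaves(node):
        if isinstance(node, str):
            return [node]
        return leaves(node[0]) + leaves(node[1])

    # accumulate leaf-to-ancestor distances recursively
    def walk(node):
        """returns {leaf: distance to this node}"""
        if isinstance(node, str):
            return {node: 0.0}
        left, right = (walk(child) for child in node)
        bl = rng.uniform(0.1, 1.0)
        br = rng.uniform(0.1, 1.0)
        left = {k: v + bl for k, v in left.items()}
        right = {k: v + br for k, v in right.items()}
        for a, da in left.items():
            for b, db in right.items():
                dist[a][b] = dist[b][a] = da + db
        side = frozenset(left) | frozenset(right)
        if 2 <= len(side) <= len(taxa) - 2:
            bipartitions.add(min(side, frozenset(taxa) - side, key=sorted))
        return {**left, **right}

    walk(topo)
    n = len(taxa)
    D = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                D[i, j] = dist[a][b]
    return D, bipartitions


def tree_bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial unrooted bipartitions, by independent recursion."""
    taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()

    def walk(nd):
        if nd.is_leaf():
            return frozenset([nd.taxon.label])
        below = frozenset()
        for c in nd.child_nodes():
            below |= walk(c)
        if 2 <= len(below) <= len(taxa) - 2:
            out.add(min(below, taxa - below, key=sorted))
        return below

    walk(tree.seed_node)
    return out


# ---------------------------------------------------------------------------
# exhaustive concordance oracle (pure set logic, independent traversal)

def oracle_concordance(species_tree, gene_trees, min_support):
    """Branch -> (concordant, conflict, uninformative) by brute enumeration."""
    sp_taxa = frozenset(lf.taxon.label for lf in species_tree.leaf_node_iter())

    def branches(tree):
        taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        found = {}

        def walk(nd):
            if nd.is_leaf():
                return frozenset([nd.taxon.label])
            below = frozenset()
            for c in nd.child_nodes():
                below |= walk(c)
            if 2 <= len(below) <= len(taxa) - 2:
                key = min(below, taxa - below, key=sorted)
                sup = None
                if nd.label is not None:
                    try:
                        sup = int(round(float(nd.label)))
                    except ValueError:
                        sup = None
                if sup is None:
                    sup = getattr(nd, "support", None)
                found.setdefault(key, sup)
            return below

        walk(tree.seed_node)
        return taxa, found

    results = {}
    sp_branch_sides = branches(species_tree)[1].keys()
    for side in sp_branch_sides:
        conc = conf = unin = 0
        for gt in gene_trees:
            gt_taxa, gt_bips = branches(gt)
            common = sp_taxa & gt_taxa
            a0 = side & common
            b0 = (sp_taxa - side) & common
            if len(a0) < 2 or len(b0) < 2 or len(common) < 4:
                unin += 1
                continue
            is_conc = False
            is_conf = False
            for gside, sup in gt_bips.items():
                if sup is not None and sup < min_support:
                    continue
                ga = gside & common
                gb = (gt_taxa - gside) & common
                if len(ga) < 2 or len(gb) < 2:
                    continue
                if {ga, gb} == {a0, b0}:
                    is_conc = True
                    break
                if ga & a0 and ga & b0 and gb & a0 and gb & b0:
                    is_conf = True
            if is_conc:
                conc += 1
            elif is_conf:
                conf += 1
            else:
                unin += 1
        results[side] = (conc, conf, unin)
    return results


# ---------------------------------------------------------------------------
# NG86 brute-force oracle (translation-table based, path enumeration)

_CODON_TABLE = {}


def _build_table():
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    tab = unambiguous_dna_by_id[1]
    for c in ("".join(p) for p in itertools.product(NUCS, repeat=3)):
        _CODON_TABLE[c] = None if c in tab.stop_codons else tab.forward_table[c]


_build_table()


def oracle_ng86(seq1: str, seq2: str):
    """(S, N, Sd, Nd) by explicit enumeration, codon by codon."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3].upper(), seq2[i:i + 3].upper()
        if any(ch not in NUCS for ch in c1 + c2):
            continue
        if _CODON_TABLE[c1] is None or _CODON_TABLE[c2] is None:
            continue
        diffs = [k for k in range(3) if c1[k] != c2[k]]
        path_results = []
        for order in itertools.permutations(diffs):
            cur, sd, nd, valid = c1, 0.0, 0.0, True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if _CODON_TABLE[nxt] is None:
                    valid = False
                    break
                if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if valid:
                path_results.append((sd, nd))
        if diffs and not path_results:
            continue  # all paths blocked by stops: codon skipped
        if path_results:
            Sd += sum(r[0] for r in path_results) / len(path_results)
            Nd += sum(r[1] for r in path_results) / len(path_results)
        # site counts, averaged over the two codons
        for c in (c1, c2):
            syn = 0.0
            for pos in range(3):
                for nuc in NUCS:
                    if nuc == c[pos]:
                        continue
                    mut = c[:pos] + nuc + c[pos + 1:]
                    if _CODON_TABLE[mut] is not None and \
                            _CODON_TABLE[mut] == _CODON_TABLE[c]:
                        syn += 1 / 3
            S += syn / 2
            N += (3 - syn) / 2
    return S, N, Sd, Nd


def random_codon_seq(rng: random.Random, n_codons: int) -> str:
    stops = {c for c, aa in _CODON_TABLE.items() if aa is None}
    codons = [c for c in _CODON_TABLE if c not in stops]
    return "".join(rng.choice(codons) for _ in range(n_codons))


def mutate_codon_seq(rng: random.Random, seq: str, n_mut: int) -> str:
    s = list(seq)
    for _ in range(n_mut):
        while True:
            pos = rng.randrange(len(s))
            new = rng.choice(NUCS)
            trial = list(s)
            trial[pos] = new
            codon = "".join(trial[3 * (pos // 3): 3 * (pos // 3) + 3])
            if _CODON_TABLE[codon] is not None:
                s = trial
                break
    return "".join(s)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def pyrng():
    return random.Random(20240901)
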