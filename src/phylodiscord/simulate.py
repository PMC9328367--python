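"""Synthetic gene-family generator with known truth.

Two deliberately separate gene-tree generators keep downstream truths
unambiguous:

* :func:`simulate_duplication_family` — birth–death of gene lineages along
  the species tree (duplication/loss, **no** coalescent discordance); the
  truth records every duplication with the species-tree branch it occurred
  on, the surviving duplication nodes, and the true ortholog partition.
* :func:`simulate_msc_gene_trees` — single-copy loci under the multispecies
  coalescent (via msprime, populations of size 1 and ploidy 1 so time is in
  coalescent units), with optional hybrid edges realized as per-gene lineage
  routing: each gene independently sends the hybrid taxon to its minor
  parent with probability ``gamma`` before the coalescent runs.

Sequences are simulated site-i.i.d. under JC69 or HKY down a gene tree;
transcriptome-like missingness is injected afterwards (whole-taxon dropout,
then per-cell gaps), so gaps are noise, not an indel model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import msprime
import numpy as np
from scipy.linalg import expm

from ._trees import parse_newick, taxon_of
from .alignment import Alignment

__all__ = [
    "HybridEdge",
    "SimulationConfig",
    "GeneDuplicationTruth",
    "GeneFamilyTruth",
    "simulate_species_tree",
    "simulate_duplication_family",
    "simulate_msc_gene_trees",
    "simulate_alignment",
    "simulate_ks_sample",
    "branch_id",
    "node_age",
]


# ---------------------------------------------------------------------------
# small helpers

def branch_id(node) -> frozenset:
    """Identify a species-tree branch by the taxa below it."""
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def node_age(node) -> float:
    """Age of a node above the tips (assumes an ultrametric tree)."""
    if node.is_leaf():
        return 0.0
    child = node.child_nodes()[0]
    return node_age(child) + (child.edge.length or 0.0)


def _annotate_ages(tree: dendropy.Tree) -> None:
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd.age_ = 0.0
        else:
            nd.age_ = max(c.age_ + (c.edge.length or 0.0) for c in nd.child_nodes())


# ---------------------------------------------------------------------------
# species tree

def simulate_species_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Rooted ultrametric pure-birth (Yule) species tree in coalescent units.

    Taxa are labelled ``sp1..spN``.  The process runs to the n-th
    speciation and then extends the present by a final Exp(n*birth_rate)
    interval (the complete-tree convention), so the expected root-to-tip
    depth is sum_{k=2..n} 1/(k*birth_rate).
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    root = dendropy.Node()
    active: list[tuple[dendropy.Node, float]] = []  # (pending node, birth time)
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    for k in range(2, n_taxa):
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(len(active)))
        node, birth = active.pop(idx)
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (n_taxa * birth_rate))
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    for node, birth in active:
        node.edge.length = t - birth
    for i, lf in enumerate(tree.leaf_node_iter(), 1):
        lf.taxon = dendropy.Taxon(label=f"sp{i}")
        tns.add_taxon(lf.taxon)
    root.edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# duplication/loss families

@dataclass
class GeneDuplicationTruth:
    """One true duplication event."""

    species_branch: frozenset      # taxa below the species branch it occurred on
    time: float                    # time along that branch (from its top)
    surviving: bool = False        # both daughters left extant descendants
    node: Optional[dendropy.Node] = None  # node in the final gene tree if surviving


@dataclass
class GeneFamilyTruth:
    """Simulator output for one gene family."""

    tree: Optional[dendropy.Tree]               # final gene tree (None if extinct)
    duplications: list[GeneDuplicationTruth]    # all events, incl. non-surviving
    ortholog_partition: list[frozenset]         # tip labels, cut at surviving dups
    n_losses: int
    total_lineage_length: float                 # summed gene-lineage branch length

    @property
    def surviving_duplications(self) -> list[GeneDuplicationTruth]:
        return [d for d in self.duplications if d.surviving]


class _GLin:
    """A gene lineage being grown: a node-in-progress of the gene tree."""

    __slots__ = ("children", "length", "is_dup", "species_branch", "label", "_truth")

    def __init__(self):
        self.children: list[_GLin] = []
        self.length = 0.0
        self.is_dup = False
        self.species_branch: Optional[frozenset] = None
        self.label: Optional[str] = None


def simulate_duplication_family(
    species_tree: dendropy.Tree,
    dup_rate: float,
    loss_rate: float,
    seed: int = 0,
) -> GeneFamilyTruth:
    """Evolve one gene family along the species tree by duplication/loss.

    Gene lineages follow the species tree exactly (no coalescent
    discordance); duplications and losses are a Poisson process per lineage
    with rates ``dup_rate`` and ``loss_rate`` per coalescent unit.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    total_rate = dup_rate + loss_rate
    events: list[GeneDuplicationTruth] = []
    stats = {"loss": 0, "length": 0.0}

    def evolve_branch(lin: _GLin, remaining: float, sbranch: frozenset, t0: float) -> list[_GLin]:
        """Grow one lineage along (the rest of) a species branch."""
        t = t0
        while True:
            dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            if dt >= remaining:
                lin.length += remaining
                stats["length"] += remaining
                return [lin]
            lin.length += dt
            stats["length"] += dt
            remaining -= dt
            t += dt
            if rng.random() < (dup_rate / total_rate if total_rate else 0.0):
                ev = GeneDuplicationTruth(species_branch=sbranch, time=t)
                events.append(ev)
                lin.is_dup = True
                lin.species_branch = sbranch
                lin._truth = ev  # type: ignore[attr-defined]
                out: list[_GLin] = []
                for _ in range(2):
                    child = _GLin()
                    lin.children.append(child)
                    out.extend(evolve_branch(child, remaining, sbranch, t))
                return out
            stats["loss"] += 1
            return []

    seq_counter: dict[str, int] = {}

    def descend(snode, lin: _GLin) -> None:
        """Lineage `lin` has just arrived at species node `snode`."""
        if snode.is_leaf():
            taxon = snode.taxon.label
            seq_counter[taxon] = seq_counter.get(taxon, 0) + 1
            lin.label = f"{taxon}@{seq_counter[taxon]}"
            return
        for child in snode.child_nodes():
            sub = _GLin()
            lin.children.append(sub)
            survivors = evolve_branch(sub, child.edge.length or 0.0, branch_id(child), 0.0)
            for s in survivors:
                descend(child, s)

    root = _GLin()
    descend(species_tree.seed_node, root)

    # prune dead lineages / suppress unary passthroughs, build dendropy tree
    def build(lin: _GLin, acc_len: float):
        if lin.label is not None:
            nd = dendropy.Node()
            nd.taxon = dendropy.Taxon(label=lin.label)
            nd.edge.length = acc_len + lin.length
            nd.is_duplication = False
            return nd
        kids = [build(c, 0.0) for c in lin.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            k = kids[0]
            k.edge.length += acc_len + lin.length
            return k
        nd = dendropy.Node()
        nd.edge.length = acc_len + lin.length
        nd.is_duplication = lin.is_dup
        nd.species_branch = lin.species_branch
        if lin.is_dup:
            truth = getattr(lin, "_truth", None)
            if truth is not None:
                truth.surviving = True
                truth.node = nd
        for k in kids:
            nd.add_child(k)
        return nd

    root_node = build(root, 0.0)
    tree = None
    partition: list[frozenset] = []
    if root_node is not None:
        tns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node = root_node
        tree.is_rooted = True
        for lf in tree.leaf_node_iter():
            tns.add_taxon(lf.taxon)
        # ortholog partition: cut both child edges at every surviving dup node
        groups: dict[int, set] = {}

        def assign(nd, gid, next_gid):
            if nd.is_leaf():
                groups.setdefault(gid, set()).add(nd.taxon.label)
                return next_gid
            if getattr(nd, "is_duplication", False):
                for c in nd.child_nodes():
                    next_gid += 1
                    next_gid = assign(c, next_gid, next_gid)
                return next_gid
            for c in nd.child_nodes():
                next_gid = assign(c, gid, next_gid)
            return next_gid

        assign(tree.seed_node, 0, 0)
        partition = [frozenset(g) for g in groups.values()]

    return GeneFamilyTruth(
        tree=tree,
        duplications=events,
        ortholog_partition=partition,
        n_losses=stats["loss"],
        total_lineage_length=stats["length"],
    )


# ---------------------------------------------------------------------------
# multispecies coalescent with optional hybrid edges

@dataclass(frozen=True)
class HybridEdge:
    """Per-gene routing of ``hybrid`` to a minor parent with prob. gamma.

    ``donor`` identifies the minor-parent branch as the set (or single
    label) of taxa below it *after* the hybrid tip is detached;
    ``attach_time`` is the age (coalescent units above the tips) at which
    the rerouted hybrid lineage joins that branch.
    """

    hybrid: str
    donor: frozenset
    attach_time: float
    gamma: float

    def __init__(self, hybrid, donor, attach_time, gamma):
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        object.__setattr__(self, "hybrid", hybrid)
        donor = frozenset([donor] if isinstance(donor, str) else donor)
        object.__setattr__(self, "donor", donor)
        object.__setattr__(self, "attach_time", float(attach_time))
        object.__setattr__(self, "gamma", float(gamma))


def _reroute(tree: dendropy.Tree, edge: HybridEdge) -> dendropy.Tree:
    """Species-tree surgery: re-attach the hybrid tip to the donor branch."""
    t = tree.clone(depth=1)
    hyb = None
    for lf in t.leaf_node_iter():
        if lf.taxon.label == edge.hybrid:
            hyb = lf
    if hyb is None:
        raise ValueError(f"hybrid taxon {edge.hybrid!r} not in species tree")
    parent = hyb.parent_node
    parent.remove_child(hyb)
    t.suppress_unifurcations()
    _annotate_ages(t)
    donor_nodes = [lf for lf in t.leaf_node_iter() if lf.taxon.label in edge.donor]
    if len(donor_nodes) != len(edge.donor):
        raise ValueError("donor taxa missing from species tree")
    mrca = t.mrca(taxa=[n.taxon for n in donor_nodes]) if len(donor_nodes) > 1 else donor_nodes[0]
    top = mrca.parent_node
    lo, hi = mrca.age_, mrca.age_ + (mrca.edge.length or 0.0)
    if not (lo <= edge.attach_time <= hi):
        raise ValueError(
            f"attach_time {edge.attach_time} outside donor branch interval [{lo}, {hi}]"
        )
    new = dendropy.Node()
    top.remove_child(mrca)
    top.add_child(new)
    new.edge.length = hi - edge.attach_time
    new.add_child(mrca)
    mrca.edge.length = edge.attach_time - lo
    hyb.edge.length = edge.attach_time
    new.add_child(hyb)
    t.taxon_namespace = tree.taxon_namespace
    return t


def _demography(tree: dendropy.Tree) -> msprime.Demography:
    """msprime demography in coalescent units (Ne = 1, ploidy 1)."""
    _annotate_ages(tree)
    dem = msprime.Demography()
    names: dict[int, str] = {}
    counter = [0]
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            name = nd.taxon.label
        else:
            name = f"anc{counter[0]}"
            counter[0] += 1
        names[id(nd)] = name
        dem.add_population(name=name, initial_size=1.0)
    for nd in tree.postorder_node_iter():
        if not nd.is_leaf():
            dem.add_population_split(
                time=nd.age_,
                derived=[names[id(c)] for c in nd.child_nodes()],
                ancestral=names[id(nd)],
            )
    dem.sort_events()
    return dem


def simulate_msc_gene_trees(
    species_tree: dendropy.Tree,
    hybrid_edges: Sequence[HybridEdge] = (),
    n_trees: int = 100,
    seed: int = 0,
) -> list[dendropy.Tree]:
    """Single-copy gene trees under the (network) multispecies coalescent.

    Each gene independently routes every hybrid taxon to its minor parent
    with probability gamma, then the standard MSC runs on the resulting
    species tree.  Deterministic per seed; branch lengths in coalescent
    units; output trees are rooted.
    """
    for e in hybrid_edges:
        if not 0.0 <= e.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = len(hybrid_edges)
    # routing pattern per gene: bitmask over hybrid edges
    if k:
        draws = rng.random((n_trees, k))
        patterns = (draws < np.array([e.gamma for e in hybrid_edges])).astype(int)
        keys = [tuple(row) for row in patterns]
    else:
        keys = [()] * n_trees

    trees_by_key: dict[tuple, list] = {}
    taxa = sorted(lf.taxon.label for lf in species_tree.leaf_node_iter())
    tns = dendropy.TaxonNamespace(taxa)
    for key in sorted(set(keys)):
        st = species_tree
        for bit, e in zip(key, hybrid_edges):
            if bit:
                st = _reroute(st, e)
        dem = _demography(st)
        count = keys.count(key)
        msp_seed = int(rng.integers(1, 2**31 - 1))
        samples = {t: 1 for t in taxa}
        reps = msprime.sim_ancestry(
            samples=samples,
            demography=dem,
            ploidy=1,
            random_seed=msp_seed,
            num_replicates=count,
        )
        out = []
        for ts in reps:
            labels = {
                u: ts.population(ts.node(u).population).metadata["name"]
                for u in ts.samples()
            }
            nwk = ts.first().as_newick(node_labels=labels)
            gt = dendropy.Tree.get(
                data=nwk,
                schema="newick",
                rooting="force-rooted",
                taxon_namespace=tns,
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
            for nd in gt.preorder_node_iter():
                nd.support = None
            out.append(gt)
        trees_by_key[key] = out

    result = []
    iters = {key: iter(v) for key, v in trees_by_key.items()}
    for key in keys:
        result.append(next(iters[key]))
    return result


# ---------------------------------------------------------------------------
# sequence simulation

@dataclass
class SimulationConfig:
    """Knobs for sequence simulation and missing-data injection."""

    length: int = 1000
    model: str = "JC69"              # "JC69" | "HKY"
    kappa: float = 2.0               # HKY transition/transversion ratio
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)  # A C G T
    scale: float = 1.0               # substitutions/site per coalescent unit
    dropout_prob: float = 0.0        # whole-taxon missing rows
    gap_prob: float = 0.0            # per-cell gaps
    seed: int = 0

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for r in (self.scale, self.dropout_prob, self.gap_prob, self.kappa):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.model not in ("JC69", "HKY"):
            raise ValueError(f"unknown model {self.model!r}")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")


_NUCS = np.frombuffer(b"ACGT", dtype="S1")


def _rate_matrix(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    pi = np.asarray(cfg.base_freqs, float)
    if cfg.model == "JC69":
        pi = np.full(4, 0.25)
        Q = np.full((4, 4), 1.0 / 3.0)
    else:  # HKY; order A C G T, transitions A<->G, C<->T
        Q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = pi[j]
                if (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1)):
                    rate *= cfg.kappa
                Q[i, j] = rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu, pi


def simulate_alignment(gene_tree: dendropy.Tree, config: SimulationConfig) -> Alignment:
    """Simulate a site-i.i.d. nucleotide alignment down ``gene_tree``.

    Branch lengths are multiplied by ``config.scale`` to convert to
    expected substitutions per site.  After simulation, taxa are dropped
    out (entire row set to '-') with ``dropout_prob`` and remaining cells
    gapped with ``gap_prob``; neither step changes the label set.
    """
    rng = np.random.default_rng(config.seed)
    Q, pi = _rate_matrix(config)
    L = config.length
    pmat_cache: dict[float, np.ndarray] = {}

    def pmat(t: float) -> np.ndarray:
        if t not in pmat_cache:
            pmat_cache[t] = expm(Q * t)
        return pmat_cache[t]

    states: dict[int, np.ndarray] = {}
    root = gene_tree.seed_node
    states[id(root)] = rng.choice(4, size=L, p=pi)
    labels, rows = [], []
    for nd in gene_tree.preorder_node_iter():
        if nd is root:
            pass
        else:
            t = (nd.edge.length or 0.0) * config.scale
            parent_states = states[id(nd.parent_node)]
            if t <= 0:
                states[id(nd)] = parent_states.copy()
            else:
                P = pmat(t)
                u = rng.random(L)
                cum = np.cumsum(P, axis=1)
                states[id(nd)] = (u[:, None] > cum[parent_states]).sum(axis=1)
        if nd.is_leaf():
            labels.append(nd.taxon.label)
            rows.append(states[id(nd)])
    data = _NUCS[np.array(rows)]
    # missing-data injection: dropout first, then gaps
    drop = rng.random(len(labels)) < config.dropout_prob
    data[drop] = b"-"
    gaps = rng.random(data.shape) < config.gap_prob
    data[gaps] = b"-"
    return Alignment(labels, data)


# ---------------------------------------------------------------------------
# Ks truth

def simulate_ks_sample(
    component_spec: Sequence[tuple[float, float, float]],
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw n Ks values from a lognormal mixture.

    ``component_spec`` is a list of (weight, mean of log-Ks, sd of log-Ks);
    weights must sum to 1.
    """
    spec = [(float(w), float(m), float(s)) for w, m, s in component_spec]
    if abs(sum(w for w, _, _ in spec) - 1.0) > 1e-9:
        raise ValueError("component weights must sum to 1")
    rng = np.random.default_rng(seed)
    comps = rng.choice(len(spec), size=n, p=[w for w, _, _ in spec])
    mus = np.array([m for _, m, _ in spec])[comps]
    sds = np.array([s for _, _, s in spec])[comps]
    return np.exp(rng.normal(mus, sds))
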