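"""Quartet sampling: QC/QD/QI branch support from a supermatrix.

For each internal species-tree branch, quartets are drawn with one taxon
from each of the four subtrees attached to the branch; the three possible
quartet topologies are scored by Jukes–Cantor likelihood (five branch
lengths optimised by bounded coordinate descent) on the quartet's
supermatrix columns.  A replicate is informative when the best topology
beats the runner-up by at least ``lnl_threshold`` log units.

Scores per branch (t0 concordant, t1/t2 discordant, over informative
replicates):

* QC = log3(3 * t0 / (t0+t1+t2)), clamped to [-1, 1]; 1 when no
  discordant replicate was seen; 0 when all three topologies are equally
  common; negative when the concordant topology is the minority.
* QD = 1 - |t1-t2| / (t1+t2); undefined (None) when t1+t2 = 0; 0 means a
  single alternative topology dominates the discordance.
* QI = (t0+t1+t2) / n_replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from ._trees import taxon_of
from .alignment import Alignment

__all__ = ["QuartetScores", "BranchQuartetScore", "quartet_sampling",
           "quartet_loglik", "best_quartet_topology"]


@dataclass
class BranchQuartetScore:
    branch: frozenset          # taxa on the child side of the branch
    t0: int
    t1: int
    t2: int
    n_uninformative: int
    n_replicates: int

    @property
    def qc(self) -> float:
        tt = self.t0 + self.t1 + self.t2
        if tt == 0:
            return 0.0
        if self.t1 + self.t2 == 0:
            return 1.0
        if self.t0 == 0:
            return -1.0
        val = math.log(3.0 * self.t0 / tt, 3)
        return max(-1.0, min(1.0, val))

    @property
    def qd(self) -> Optional[float]:
        if self.t1 + self.t2 == 0:
            return None
        return 1.0 - abs(self.t1 - self.t2) / (self.t1 + self.t2)

    @property
    def qi(self) -> float:
        return (self.t0 + self.t1 + self.t2) / self.n_replicates


@dataclass
class QuartetScores:
    branches: list[BranchQuartetScore]

    def by_branch(self) -> dict[frozenset, BranchQuartetScore]:
        return {b.branch: b for b in self.branches}


# ---------------------------------------------------------------------------
# quartet likelihood under JC69

_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T


def _patterns(alignment: Alignment, quartet: Sequence[str]):
    """Collapse the quartet's columns to unambiguous site patterns."""
    rows = np.stack([alignment.row(t).view(np.uint8) for t in quartet])
    valid = np.isin(rows, list(_CODE)).all(axis=0)
    rows = rows[:, valid]
    conv = np.zeros(256, dtype=np.int8)
    for k, v in _CODE.items():
        conv[k] = v
    states = conv[rows]
    key = states[0] * 64 + states[1] * 16 + states[2] * 4 + states[3]
    uniq, counts = np.unique(key, return_counts=True)
    pats = np.stack([(uniq // 64) % 4, (uniq // 16) % 4, (uniq // 4) % 4, uniq % 4])
    return pats, counts.astype(float)


def _jc_p(t: float) -> tuple[float, float]:
    e = math.exp(-4.0 * t / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def quartet_loglik(pats, counts, br: Sequence[float]) -> float:
    """ln L of topology ((0,1),(2,3)) with branches (l0,l1,l2,l3,lm)."""
    a, b, c, d = pats
    m = pats.shape[1]
    same_diff = [_jc_p(t) for t in br]
    # conditional likelihoods at the two internal nodes
    Lx = np.empty((4, m))
    Ly = np.empty((4, m))
    for sx in range(4):
        pa = np.where(a == sx, same_diff[0][0], same_diff[0][1])
        pb = np.where(b == sx, same_diff[1][0], same_diff[1][1])
        Lx[sx] = pa * pb
    for sy in range(4):
        pc = np.where(c == sy, same_diff[2][0], same_diff[2][1])
        pd = np.where(d == sy, same_diff[3][0], same_diff[3][1])
        Ly[sy] = pc * pd
    psame, pdiff = same_diff[4]
    Pm = np.full((4, 4), pdiff)
    np.fill_diagonal(Pm, psame)
    site = 0.25 * np.einsum("im,ij,jm->m", Lx, Pm, Ly)
    return float(np.dot(counts, np.log(np.maximum(site, 1e-300))))


def _optimize_topology(pats, counts, n_passes: int = 3, tol: float = 1e-4) -> float:
    br = [0.1] * 5
    prev = quartet_loglik(pats, counts, br)
    for _ in range(n_passes):
        for i in range(5):
            def neg(x, i=i):
                trial = list(br)
                trial[i] = x
                return -quartet_loglik(pats, counts, trial)
            res = minimize_scalar(neg, bounds=(1e-8, 10.0), method="bounded",
                                  options={"xatol": tol, "maxiter": 24})
            br[i] = float(res.x)
        cur = quartet_loglik(pats, counts, br)
        if cur - prev < tol:
            break
        prev = cur
    return quartet_loglik(pats, counts, br)


def best_quartet_topology(
    alignment: Alignment,
    quartet: Sequence[str],
    lnl_threshold: float = 2.0,
):
    """(winner index or None, lnLs) for the 3 topologies of a quartet.

    Topology 0 = ((q0,q1),(q2,q3)); 1 = ((q0,q2),(q1,q3));
    2 = ((q0,q3),(q1,q2)).  Winner is None when the replicate is
    uninformative (margin < threshold or no usable sites).
    """
    pats, counts = _patterns(alignment, quartet)
    if counts.sum() == 0:
        return None, (float("-inf"),) * 3
    orders = [(0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2)]
    lnls = []
    for order in orders:
        lnls.append(_optimize_topology(pats[list(order)], counts))
    ranked = sorted(range(3), key=lambda k: -lnls[k])
    if lnls[ranked[0]] - lnls[ranked[1]] < lnl_threshold:
        return None, tuple(lnls)
    return ranked[0], tuple(lnls)


# ---------------------------------------------------------------------------
# branch machinery

def _branch_quartet_sets(species_tree: dendropy.Tree):
    """Per internal branch: the four taxon subsets around it.

    Yields (child-side taxa, (S1, S2, S3, S4)) with S1, S2 the child's two
    daughter subtrees and S3, S4 the two subtrees on the parent side.
    Branches where any subset is empty are skipped.
    """
    t = species_tree.clone(depth=1)
    t.deroot()
    all_taxa = frozenset(taxon_of(lf.taxon.label) for lf in t.leaf_node_iter())

    def leafset(nd):
        return frozenset(taxon_of(lf.taxon.label) for lf in nd.leaf_iter())

    for nd in t.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        kids = nd.child_nodes()
        if len(kids) != 2:
            continue
        s1, s2 = leafset(kids[0]), leafset(kids[1])
        parent = nd.parent_node
        sibs = [c for c in parent.child_nodes() if c is not nd]
        if parent.parent_node is None:
            if len(sibs) != 2:
                continue
            s3, s4 = leafset(sibs[0]), leafset(sibs[1])
        else:
            if len(sibs) != 1:
                continue
            s3 = leafset(sibs[0])
            s4 = all_taxa - s1 - s2 - s3
        if not (s1 and s2 and s3 and s4):
            continue
        yield s1 | s2, (s1, s2, s3, s4)


def quartet_sampling(
    supermatrix: Alignment,
    species_tree: dendropy.Tree,
    n_replicates: int = 1000,
    lnl_threshold: float = 2.0,
    seed: int = 0,
) -> QuartetScores:
    """Quartet-sampling scores for every internal branch of the species tree."""
    rng = np.random.default_rng(seed)
    rows = set(supermatrix.labels)
    scores = []
    cache: dict[tuple, Optional[int]] = {}
    for branch, subsets in _branch_quartet_sets(species_tree):
        subsets = [sorted(s & rows) for s in subsets]
        if any(len(s) == 0 for s in subsets):
            continue
        t0 = t1 = t2 = 0
        unin = 0
        for _ in range(n_replicates):
            quartet = tuple(s[rng.integers(len(s))] for s in subsets)
            if quartet in cache:
                winner = cache[quartet]
            else:
                winner, _ = best_quartet_topology(supermatrix, quartet, lnl_threshold)
                cache[quartet] = winner
            if winner is None:
                unin += 1
            elif winner == 0:
                t0 += 1
            elif winner == 1:
                t1 += 1
            else:
                t2 += 1
        scores.append(BranchQuartetScore(
            branch=branch, t0=t0, t1=t1, t2=t2,
            n_uninformative=unin, n_replicates=n_replicates,
        ))
    return QuartetScores(branches=scores)
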