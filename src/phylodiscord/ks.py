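"""Synonymous-distance (Ks) machinery for WGD detection.

Pairwise Ks is estimated with the Nei–Gojobori (NG86) counting method on
in-frame codon alignments: per-codon synonymous/nonsynonymous site
fractions from the standard genetic code, averaged over both sequences;
differences counted by averaging over all minimal mutation paths between
the two codons (paths through stop codons are excluded; changes to stop
codons count as nonsynonymous in site fractions); pS = Sd/S corrected by
Jukes–Cantor: Ks = -(3/4) ln(1 - 4 pS / 3).

Per-taxon Ks distributions over within-cluster paralog pairs are fitted on
ln(Ks) with a Gaussian mixture (EM with seeded random restarts), the
component count selected by BIC — clustered Ks peaks indicate whole-genome
duplications.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "KsEstimate",
    "KsMixtureFit",
    "ks_pairwise",
    "ks_distribution",
    "fit_ks_mixture",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_NUC = "ACGT"


def _aa(codon: str) -> Optional[str]:
    if codon in _STOPS:
        return None
    return _TABLE.forward_table[codon]


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (stop-yielding changes = nonsyn)."""
    if codon in _STOPS:
        return 0.0
    s = 0.0
    aa0 = _aa(codon)
    for pos in range(3):
        for nuc in _NUC:
            if nuc == codon[pos]:
                continue
            mut = codon[:pos] + nuc + codon[pos + 1:]
            if mut not in _STOPS and _aa(mut) == aa0:
                s += 1.0 / 3.0
    return s


_SYN_SITES = {"".join(c): None for c in itertools.product(_NUC, repeat=3)}
for _c in _SYN_SITES:
    _SYN_SITES[_c] = _syn_sites(_c)


def _path_counts(c1: str, c2: str) -> Optional[tuple[float, float]]:
    """(syn, nonsyn) differences averaged over valid minimal paths."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                ok = False
                break
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


@dataclass
class KsEstimate:
    """NG86 estimate for one sequence pair."""

    label_a: str
    label_b: str
    S: float               # synonymous sites (averaged over both sequences)
    N: float               # nonsynonymous sites
    Sd: float              # synonymous differences
    Nd: float              # nonsynonymous differences
    n_codons: int          # codons compared (ambiguity/stop codons skipped)
    saturated: bool = False

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0

    @property
    def ks(self) -> Optional[float]:
        if self.saturated:
            return None
        p = self.pS
        return max(0.0, -0.75 * math.log(1.0 - 4.0 * p / 3.0))

    @property
    def ka(self) -> Optional[float]:
        p = self.Nd / self.N if self.N > 0 else 0.0
        if p >= 0.75:
            return None
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ks_pairwise(cds_a: str, cds_b: str, label_a: str = "a", label_b: str = "b") -> KsEstimate:
    """NG86 synonymous distance between two aligned in-frame CDS strings."""
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("alignment length not divisible by 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(ch not in _NUC for ch in ca + cb):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        counts = _path_counts(ca, cb)
        if counts is None:
            continue
        sa, sb = _SYN_SITES[ca], _SYN_SITES[cb]
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        Sd += counts[0]
        Nd += counts[1]
        n_codons += 1
    est = KsEstimate(label_a, label_b, S, N, Sd, Nd, n_codons)
    if est.S <= 0 or est.pS >= 0.75:
        est.saturated = True
    return est


def ks_distribution(
    clusters: dict[str, Sequence[tuple[str, str]]],
    taxon: str,
    ks_min: float = 1e-4,
    ks_max: float = 3.0,
) -> list[float]:
    """Ks for every within-taxon pair co-occurring in a cluster.

    ``clusters`` maps cluster id -> [(tip label, CDS string), ...]; tip
    labels follow the ``taxon@seqid`` convention.  Saturated pairs and
    values outside (ks_min, ks_max] are excluded (near-zero pairs are
    alleles/isoforms, large values are beyond saturation-safe range).
    """
    out = []
    for _cid, seqs in sorted(clusters.items()):
        mine = [(lab, s) for lab, s in seqs if lab.split("@", 1)[0] == taxon]
        for (la, sa), (lb, sb) in itertools.combinations(mine, 2):
            est = ks_pairwise(sa, sb, la, lb)
            if est.saturated:
                continue
            k = est.ks
            if k is not None and ks_min < k <= ks_max:
                out.append(k)
    return out


# ---------------------------------------------------------------------------
# Gaussian mixture on ln(Ks)

@dataclass
class KsMixtureFit:
    """EM fit of a k-component Gaussian mixture to ln(Ks)."""

    weights: np.ndarray
    means: np.ndarray          # on the ln(Ks) scale
    sds: np.ndarray
    log_likelihood: float
    bic: float
    k: int
    n: int
    ll_trajectory: list[float] = field(default_factory=list)

    @property
    def ks_peaks(self) -> np.ndarray:
        """Component locations back on the Ks scale."""
        return np.exp(self.means)


def _em_1d(x: np.ndarray, k: int, rng, n_iter: int = 300, tol: float = 1e-8):
    n = x.size
    # init: means from random data points, common sd
    mu = np.sort(rng.choice(x, size=k, replace=False))
    sd = np.full(k, max(x.std(), 1e-3))
    w = np.full(k, 1.0 / k)
    ll_prev = -np.inf
    traj = []
    for _ in range(n_iter):
        logp = (
            np.log(w)[None, :]
            - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
            - np.log(sd)[None, :]
            - 0.5 * math.log(2 * math.pi)
        )
        mx = logp.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logp - mx).sum(axis=1))
        ll = float(lse.sum())
        traj.append(ll)
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, 1e-8))
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            break
        ll_prev = ll
    return w, mu, sd, traj


def fit_ks_mixture(
    ks_values: Sequence[float],
    k_max: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    min_values: int = 50,
) -> KsMixtureFit:
    """Fit 1..k_max Gaussian components to ln(Ks); select k by lowest BIC.

    Each k gets ``n_restarts`` seeded random initialisations; the EM
    log-likelihood trajectory is checked to be non-decreasing on every run.
    """
    x = np.asarray([v for v in ks_values if v > 0], float)
    if x.size < min_values:
        raise ValueError(
            f"need at least {min_values} positive Ks values for a stable fit "
            f"(got {x.size})"
        )
    x = np.log(x)
    rng = np.random.default_rng(seed)
    best: Optional[KsMixtureFit] = None
    for k in range(1, k_max + 1):
        best_k = None
        for _ in range(n_restarts):
            w, mu, sd, traj = _em_1d(x, k, rng)
            diffs = np.diff(traj)
            assert (diffs >= -1e-6).all(), "EM log-likelihood decreased"
            ll = traj[-1]
            if best_k is None or ll > best_k[3][-1]:
                best_k = (w, mu, sd, traj)
        w, mu, sd, traj = best_k
        ll = traj[-1]
        p = 3 * k - 1
        bic = -2.0 * ll + p * math.log(x.size)
        order = np.argsort(mu)
        fit = KsMixtureFit(
            weights=w[order], means=mu[order], sds=sd[order],
            log_likelihood=ll, bic=bic, k=k, n=int(x.size),
            ll_trajectory=traj,
        )
        if best is None or fit.bic < best.bic:
            best = fit
    return best


def plot_ks_mixture(ks_values, fit: KsMixtureFit, path: str, bins: int = 60) -> None:
    """Optional histogram + component curves (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    x = np.log(np.asarray([v for v in ks_values if v > 0], float))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(x, bins=bins, density=True, color="0.8")
    grid = np.linspace(x.min(), x.max(), 400)
    for w, m, s in zip(fit.weights, fit.means, fit.sds):
        ax.plot(grid, w * norm.pdf(grid, m, s), lw=2,
                label=f"Ks peak at {math.exp(m):.2f}")
    ax.set_xlabel("ln(Ks)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
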