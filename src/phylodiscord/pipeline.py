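"""End-to-end orchestration: simulate -> curate -> trees -> orthology ->
concordance -> duplications/Ks -> triplets.

A single master seed drives everything; per-stage seeds are derived by
hashing the stage name, so re-running a config reproduces every output.
Filter thresholds default to the values used for 24-taxon
transcriptome/genome matrices; :meth:`RunConfig.toy` scales them for
small simulated datasets.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import yaml

from . import __version__
from ._trees import to_newick
from .alignment import Alignment
from .concordance import map_bipartitions
from .curation import (
    cut_deep_paralogs,
    filter_cluster_occupancy,
    mask_same_taxon_tips,
    remove_spurious_tips,
    trim_columns,
)
from .duplications import duplication_percentages, extract_rooted_clades, map_duplications
from .genetrees import bootstrap_support, concatenate, filter_ortholog_alignment
from .ks import fit_ks_mixture, ks_distribution
from .orthology import MORejection, filter_orthologs, prune_mo, root_by_outgroups
from .quartet import quartet_sampling
from .reticulation import scan_all_triplets
from .simulate import (
    SimulationConfig,
    branch_id,
    simulate_alignment,
    simulate_duplication_family,
    simulate_species_tree,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (master_seed * 2654435761)) % (2**31 - 1)


@dataclass
class RunConfig:
    """All thresholds of the pipeline, defaulting to 24-taxon-scale values."""

    # simulation
    n_ingroup: int = 22
    n_outgroup: int = 2
    n_families: int = 50
    dup_rate: float = 0.2
    loss_rate: float = 0.1
    alignment_length: int = 999   # divisible by 3 for the Ks stage
    subs_per_coal_unit: float = 0.15
    dropout_prob: float = 0.05
    gap_prob: float = 0.05
    # curation
    cluster_min_taxa: int = 20
    homolog_trim_max_missing: float = 0.9
    spurious_absolute: float = 1.5
    spurious_relative: float = 10.0
    deep_paralog_cutoff: float = 0.25
    deep_paralog_min_taxa: int = 20
    # gene trees
    bootstrap_reps: int = 200
    # orthology
    mo_min_taxa: int = 15
    # ortholog alignment filters
    ortholog_trim_max_missing: float = 0.2
    ortholog_min_length: int = 1000
    require_all_taxa: bool = True
    # concordance
    min_bipartition_support: int = 50
    run_quartet_sampling: bool = False
    qs_replicates: int = 1000
    qs_lnl_threshold: float = 2.0
    # duplications / Ks
    clade_min_avg_support: float = 50.0
    clade_min_taxa: int = 15
    dup_min_overlap: int = 2
    ks_k_max: int = 3
    # reticulation
    alpha: float = 0.05
    # plumbing
    seed: int = 0
    outdir: Optional[str] = None
    outgroup_taxa: tuple = ()

    @classmethod
    def toy(cls, seed: int = 0, outdir: Optional[str] = None) -> "RunConfig":
        """Scaled-down profile for ~8-taxon simulated runs."""
        return cls(
            n_ingroup=6, n_outgroup=2, n_families=30,
            subs_per_coal_unit=0.05,
            cluster_min_taxa=6, deep_paralog_min_taxa=6,
            bootstrap_reps=50, mo_min_taxa=5,
            ortholog_min_length=200, require_all_taxa=False,
            clade_min_taxa=4, qs_replicates=100,
            seed=seed, outdir=outdir,
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outgroup_taxa" in raw:
            raw["outgroup_taxa"] = tuple(raw["outgroup_taxa"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outgroup_taxa"] = list(d["outgroup_taxa"])
        return d


@dataclass
class RunManifest:
    seed: int
    version: str
    stages: list = field(default_factory=list)   # (stage, n_in, n_out)
    parameters: dict = field(default_factory=dict)

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        self.stages.append({"stage": stage, "n_in": n_in, "n_out": n_out})

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def species_tree_with_outgroup(
    n_ingroup: int, n_outgroup: int, seed: int, stem: float = 1.0
) -> tuple[dendropy.Tree, list[str]]:
    """Ultrametric species tree: a Yule ingroup plus an outgroup clade.

    Outgroups are labelled og1..ogM and attach above the ingroup root at
    ingroup depth + ``stem`` coalescent units.  Returns (tree, outgroups).
    """
    in_tree = simulate_species_tree(n_ingroup, birth_rate=1.0, seed=seed)
    depth = max(lf.distance_from_root() for lf in in_tree.leaf_node_iter())
    root_age = depth + stem
    ogs = [f"og{i}" for i in range(1, n_outgroup + 1)]
    # outgroup ladder with splits at 0.4, 0.8, ... below the attach point
    def ladder(names, top_age):
        if len(names) == 1:
            return f"{names[0]}:{top_age:.8f}"
        inner_age = 0.4 * (len(names) - 1)
        inner = ladder(names[:-1], inner_age)
        return f"({inner},{names[-1]}:{inner_age:.8f}):{top_age - inner_age:.8f}"
    in_nwk = to_newick(in_tree).rstrip(";")
    nwk = f"({in_nwk}:{stem:.8f},{ladder(ogs, root_age)});"
    tree = dendropy.Tree.get(
        data=nwk, schema="newick", rooting="force-rooted",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )
    for nd in tree.preorder_node_iter():
        nd.support = None
        nd.label = None
    return tree, ogs


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in fixed order; returns the run manifest."""
    manifest = RunManifest(seed=config.seed, version=__version__,
                           parameters=config.to_dict())
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage, item, action, reason=""):
        log_lines.append(f"{stage}\t{item}\t{action}\t{reason}")

    # ---- simulate -------------------------------------------------------
    sp_tree, ogs = species_tree_with_outgroup(
        config.n_ingroup, config.n_outgroup, stage_seed(config.seed, "species_tree")
    )
    outgroups = list(config.outgroup_taxa) or ogs
    all_taxa = sorted(lf.taxon.label for lf in sp_tree.leaf_node_iter())
    families = []
    for i in range(config.n_families):
        fam = simulate_duplication_family(
            sp_tree, config.dup_rate, config.loss_rate,
            seed=stage_seed(config.seed, f"family{i}"),
        )
        if fam.tree is None or len(fam.tree.leaf_nodes()) < 4:
            log("simulate", f"fam{i}", "skipped", "extinct-or-tiny")
            continue
        cfg = SimulationConfig(
            length=config.alignment_length,
            scale=config.subs_per_coal_unit,
            dropout_prob=config.dropout_prob,
            gap_prob=config.gap_prob,
            seed=stage_seed(config.seed, f"aln{i}"),
        )
        aln = simulate_alignment(fam.tree, cfg)
        families.append((f"fam{i}", fam, aln))
    manifest.record("simulate", config.n_families, len(families))

    # ---- cluster occupancy + trimming -----------------------------------
    clusters = []
    for fid, fam, aln in families:
        if not filter_cluster_occupancy(aln.labels, config.cluster_min_taxa):
            log("occupancy", fid, "discarded", "too few taxa")
            continue
        trimmed = trim_columns(aln, config.homolog_trim_max_missing)
        clusters.append((fid, fam, trimmed))
    manifest.record("cluster_filter", len(families), len(clusters))

    # ---- homolog trees + curation ---------------------------------------
    homologs = []
    for fid, fam, aln in clusters:
        try:
            tree = bootstrap_support(
                aln, n_reps=config.bootstrap_reps,
                seed=stage_seed(config.seed, f"bs{fid}"),
            )
        except ValueError as exc:
            log("genetrees", fid, "failed", str(exc))
            continue
        tips0 = len(tree.leaf_nodes())
        tree = mask_same_taxon_tips(tree, aln)
        tree = remove_spurious_tips(
            tree, config.spurious_absolute, config.spurious_relative
        )
        subtrees = cut_deep_paralogs(
            tree, config.deep_paralog_cutoff, config.deep_paralog_min_taxa
        )
        for k, st in enumerate(subtrees):
            homologs.append((f"{fid}.{k}", fam, aln, st))
        log("curate", fid, "kept", f"{tips0}->{len(subtrees)} subtrees")
    manifest.record("curation", len(clusters), len(homologs))

    # ---- orthology (MO) -------------------------------------------------
    orthologs = []
    for hid, fam, aln, tree in homologs:
        try:
            rooted = root_by_outgroups(tree, outgroups)
        except MORejection as rej:
            log("orthology", hid, "rejected", rej.reason.name)
            continue
        group = prune_mo(rooted, aln, source_id=hid)
        orthologs.append((hid, fam, aln, group))
    groups = filter_orthologs([g for _, _, _, g in orthologs], config.mo_min_taxa)
    kept_ids = {g.source_id for g in groups}
    orthologs = [o for o in orthologs if o[3].source_id in kept_ids]
    manifest.record("orthology", len(homologs), len(orthologs))

    # ---- ortholog alignments + supermatrix ------------------------------
    ortho_alns, ortho_trees = [], []
    required = set(all_taxa) if config.require_all_taxa else set()
    for hid, fam, aln, group in orthologs:
        labels = [l for l in aln.labels
                  if l in {f"{t}@{s}" for t, s in group.members}]
        sub = aln.subset(labels)
        sub = trim_columns(sub, config.ortholog_trim_max_missing)
        if not filter_ortholog_alignment(sub, config.ortholog_min_length, required):
            log("ortho_filter", hid, "discarded", "length-or-taxa")
            continue
        gt = bootstrap_support(
            sub, n_reps=config.bootstrap_reps,
            seed=stage_seed(config.seed, f"obs{hid}"),
        )
        ortho_alns.append(sub)
        ortho_trees.append(gt)
    manifest.record("ortholog_filter", len(orthologs), len(ortho_alns))

    supermatrix, occupancy, partitions = (
        concatenate(ortho_alns) if ortho_alns else (None, float("nan"), {})
    )
    if supermatrix is not None:
        manifest.parameters["supermatrix_columns"] = int(supermatrix.n_cols)
        manifest.parameters["supermatrix_occupancy"] = float(round(occupancy * 100, 2))

    # ---- concordance ----------------------------------------------------
    summary = map_bipartitions(sp_tree, ortho_trees, config.min_bipartition_support)
    manifest.record("concordance", len(ortho_trees), len(summary.branches))

    qs = None
    if config.run_quartet_sampling and supermatrix is not None:
        qs = quartet_sampling(
            supermatrix, sp_tree, config.qs_replicates,
            config.qs_lnl_threshold, stage_seed(config.seed, "qs"),
        )
        manifest.record("quartet_sampling", len(qs.branches), len(qs.branches))

    # ---- duplications ---------------------------------------------------
    clades, events = [], []
    for hid, fam, aln, tree in homologs:
        try:
            cl = extract_rooted_clades(
                tree, outgroups, config.clade_min_avg_support,
                config.clade_min_taxa, clade_prefix=f"{hid}c",
            )
        except ValueError:
            continue
        for c in cl:
            clades.append(c)
            events.extend(map_duplications(c, sp_tree, config.dup_min_overlap))
    percentages = duplication_percentages(events, clades, sp_tree)
    manifest.record("duplications", len(clades), len(events))

    # ---- Ks -------------------------------------------------------------
    cluster_seqs = {
        fid: [(lab, aln.sequence(lab)) for lab in aln.labels]
        for fid, fam, aln in clusters
    }
    ks_by_taxon = {}
    for taxon in all_taxa:
        vals = ks_distribution(cluster_seqs, taxon)
        if vals:
            ks_by_taxon[taxon] = vals
    fits = {}
    for taxon, vals in ks_by_taxon.items():
        try:
            fits[taxon] = fit_ks_mixture(
                vals, config.ks_k_max, seed=stage_seed(config.seed, f"ks{taxon}")
            )
        except ValueError:
            pass
    manifest.record("ks", len(ks_by_taxon), len(fits))

    # ---- reticulation ---------------------------------------------------
    triplet_table = None
    if len(ortho_trees) > 0 and len(all_taxa) >= 4:
        triplet_table = scan_all_triplets(ortho_trees, sp_tree, config.alpha)
        manifest.record("reticulation", len(ortho_trees), len(triplet_table))

    # ---- outputs --------------------------------------------------------
    if outdir:
        (outdir / "species_tree.nwk").write_text(to_newick(sp_tree) + "\n")
        with open(outdir / "curation_log.tsv", "w") as fh:
            fh.write("stage\titem\taction\treason\n")
            fh.write("\n".join(log_lines) + "\n")
        if supermatrix is not None:
            supermatrix.to_phylip(str(outdir / "supermatrix.phy"))
            from .genetrees import write_partitions
            write_partitions(partitions, str(outdir / "partitions.txt"))
        with open(outdir / "gene_trees.nwk", "w") as fh:
            for gt in ortho_trees:
                fh.write(to_newick(gt) + "\n")
        with open(outdir / "concordance.tsv", "w") as fh:
            fh.write("branch\tconcordant\ttop_alt\tother_conflict\tuninformative\n")
            for b in summary.branches:
                fh.write(
                    f"{'|'.join(sorted(b.branch))}\t{b.n_concordant}\t"
                    f"{b.n_top_alternative}\t{b.n_other_conflict}\t"
                    f"{b.n_uninformative}\n"
                )
        if qs is not None:
            with open(outdir / "quartet_scores.tsv", "w") as fh:
                fh.write("branch\tQC\tQD\tQI\tt0\tt1\tt2\n")
                for b in qs.branches:
                    qd = "NA" if b.qd is None else f"{b.qd:.3f}"
                    fh.write(
                        f"{'|'.join(sorted(b.branch))}\t{b.qc:.3f}\t{qd}\t"
                        f"{b.qi:.3f}\t{b.t0}\t{b.t1}\t{b.t2}\n"
                    )
        with open(outdir / "duplications.tsv", "w") as fh:
            fh.write("clade\tbranch\tn_overlap\n")
            for ev in events:
                fh.write(
                    f"{ev.clade_id}\t{'|'.join(sorted(ev.species_branch))}\t"
                    f"{ev.n_overlap}\n"
                )
        with open(outdir / "duplication_percentages.tsv", "w") as fh:
            fh.write("branch\tcount\tpercent\n")
            for branch, (count, pct) in sorted(
                percentages.items(), key=lambda kv: sorted(kv[0])
            ):
                p = "NA" if pct is None else f"{pct:.2f}"
                fh.write(f"{'|'.join(sorted(branch))}\t{count}\t{p}\n")
        with open(outdir / "ks_mixtures.tsv", "w") as fh:
            fh.write("taxon\tk\tweights\tks_peaks\n")
            for taxon, fit in sorted(fits.items()):
                w = ",".join(f"{x:.3f}" for x in fit.weights)
                pk = ",".join(f"{x:.4f}" for x in fit.ks_peaks)
                fh.write(f"{taxon}\t{fit.k}\t{w}\t{pk}\n")
        if triplet_table is not None:
            triplet_table.to_csv(outdir / "triplets.tsv", sep="\t", index=False)
        (outdir / "manifest.yaml").write_text(manifest.to_yaml())
    return manifest
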