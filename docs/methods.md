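# Methods

This note documents the models, estimators and numerical choices behind
`phylodiscord`, and what its simulation-based tests do and do not
demonstrate about real data.

## Scope and design

The package re-creates, as a self-contained and testable pipeline, the
analysis chain used in phylotranscriptomic studies of gene-tree
discordance: homolog-cluster curation, tree-based orthology inference,
gene-tree/species-tree concordance accounting, quartet sampling,
gene-duplication mapping with Ks mixture models, and triplet-based
introgression tests. External heavyweight tools that such studies delegate
to (ML tree searches, ASTRAL, PhyloNet, HyDe, TreeShrink) are deliberately
not wrapped or re-implemented; each is replaced by a transparent,
oracle-testable stage documented below. Every stage runs on simulated
gene families with known truth, so each guarantee is checked against an
independent oracle rather than against opaque reference output.

## Synthetic data

Two gene-tree generators are kept separate so each downstream truth is
unambiguous.

**Species trees** are pure-birth (Yule) trees in coalescent units,
simulated by explicit interval sampling: with `k` lineages the next
speciation waits Exp(k·λ); after the n-th lineage appears the present is
extended by a final Exp(n·λ) interval. The expected root-to-tip depth is
therefore exactly Σ_{k=2..n} 1/(kλ), which the tests check over 100
replicates. (An off-the-shelf birth–death simulator was tried first; its
stopping convention did not match this closed form, so the ~30-line
sampler is authored here and the closed form is the contract.)

**Duplication/loss families** evolve gene lineages along the species tree
under per-lineage Poisson duplication (λd) and loss (λl) — no coalescent
discordance, so the true duplication branch, the loss count, and the true
ortholog partition (obtained by cutting the gene tree at every surviving
duplication node) are recorded exactly. The expected number of events is
λd times the total simulated lineage length, giving a Poisson oracle for
the generator itself. Note one structural fact used by the tests:
duplications on *terminal* species branches are invisible to any
two-taxon-overlap mapping rule, because both daughter clades carry the
same single taxon.

**Single-copy coalescent gene trees** come from msprime with one haploid
sample per species and all population sizes set to 1, so time is in
coalescent units and the classic triplet probabilities hold: a species
triplet with internal branch t yields each minor rooted topology with
probability (1/3)e^(−t). Hybridization is modelled as per-gene lineage
routing: each gene independently re-attaches the hybrid tip to its minor
parent (at the specified branch and time) with probability γ, then the
standard MSC runs — the standard network-MSC convention. Routing is
implemented by species-tree surgery plus batched msprime replicates per
routing pattern, deterministic per seed.

**Sequences** are simulated site-i.i.d. under JC69 or HKY (rate matrix
normalised to one expected substitution per site at equilibrium; branch
lengths scaled from coalescent units by a single configurable scalar).
Missing data mimics transcriptome matrices: whole-taxon dropout first,
then i.i.d. per-cell gaps. There is no indel model — gaps are injected
noise — and no codon-level simulation; Ks truth is generated directly at
the Ks level as a lognormal mixture.

What this does *not* emulate: real assemblies' chimeric contigs,
alignment error, base-composition heterogeneity, rate variation across
sites and lineages, and selection. Passing tests demonstrate the
correctness of the algorithms under their stated models, not robustness
to all artifacts of real transcriptome data.

## Homolog curation

Fixed stage order: occupancy filter → column trim → (tree estimation) →
same-taxon tip masking → long-tip removal → deep-paralog cutting.

* *Occupancy*: keep clusters with at least `min_taxa` distinct taxa
  (default 20, designed for 24-taxon matrices).
* *Column trimming*: remove columns whose missing fraction ({-, N, ?},
  case-insensitive) strictly exceeds the threshold — 0.9 for homolog
  alignments, 0.2 for ortholog alignments. "More than" is strict: a
  column at exactly the threshold is kept.
* *Same-taxon tip masking*: two tips of one taxon are redundant when the
  path between them passes at most one clade containing other taxa; the
  tip with more unambiguous characters is kept (ties broken by
  lexicographic seqid), iterated to fixpoint. On rooted trees this
  collapses both monophyletic groups and one-clade paraphyletic grades;
  on unrooted (basal-trifurcation) trees the rule is symmetric and
  slightly more conservative, since "outside" is undefined there.
* *Long-tip removal* replaces a published outlier-detection tool with an
  explicit rule: a terminal branch longer than
  max(absolute_cutoff, relative_factor × median terminal length) is
  spurious; one pass; trees with fewer than 4 tips are left alone. The
  planted-outlier simulation (20× median, factor 10) shows full recall
  with zero false removals — for that planted scenario only.
* *Deep-paralog cutting* operates on the unrooted tree; a basal
  bifurcation is collapsed first so the two root edges are treated as the
  single unrooted edge they represent (their lengths add). Every internal
  edge strictly longer than the cutoff (default 0.25 substitutions/site)
  is cut; components with at least `min_subtree_taxa` distinct taxa
  survive. Each output is re-checked to contain no internal edge above
  the cutoff.

## Gene trees

Gene trees are estimated by JC69 distances (pairwise deletion; ambiguity
set {-, N, ?}) and neighbor joining, with nonparametric bootstrap support
(column resampling; support = replicate frequency × 100, floored).
Saturated pairs (p ≥ 3/4) are flagged and assigned a configurable ceiling
(default 5.0 subs/site); NJ refuses saturated input unless told otherwise.
Negative NJ branch lengths are clamped to zero at join time with the
deficit moved to the sister branch. NJ is authored here because the
clamping rule is part of the contract; dendropy's NJ serves as an
independent cross-check on additive matrices in the tests, where both
must recover the generating topology exactly.

This stage deliberately stands in for ML tree inference: the downstream
concordance machinery is agnostic to how gene trees were estimated, and
externally estimated newick trees can be supplied instead at any point.

The supermatrix concatenates per-locus alignments keyed by taxon, filling
absent taxa with `?`; occupancy is the fraction of non-missing cells.
Partition bookkeeping is 0-based half-open internally and written in the
RAxML dialect (1-based inclusive) for interoperability.

## MO orthology

Monophyletic-outgroup pruning: a homolog tree is accepted only if the
outgroup taxa present are single-copy and there is an unrooted edge
separating exactly the outgroup tips (monophyly is evaluated on the taxa
actually present; a single outgroup tip suffices). The tree is rooted on
that edge and traversed from the root; at every node whose daughters
share at least one taxon (the duplication criterion), the daughter with
fewer distinct taxa is deleted — ties broken by tip count, then total
unambiguous characters, then lexicographic seqid list, for full
determinism. The output has at most one sequence per taxon (asserted on
every run).

Guarantees verified by simulation: on lossless families the full taxon
set survives and no retained pair coalesces at a duplication node
(precision 100%); with loss at λl ≤ λd, ortholog-pair precision against
the recorded truth stays ≥ 95% while recall may drop — precision, not
recall, is the MO guarantee. Families whose outgroup was itself
duplicated are rejected by the single-copy requirement; on the 8-taxon
simulation with λd = 0.3 roughly half the families root cleanly.

## Concordance and quartet sampling

For each internal species-tree branch, each gene tree is classified by
restricting the branch's bipartition to the shared taxon set: concordant
if the gene tree contains that restricted bipartition with support at or
above the threshold (default 50); conflicting if it contains a supported,
informative bipartition incompatible with it (standard four-intersection
criterion); otherwise uninformative — which merges "no relevant
bipartition" and "support below threshold", matching the usual gray
pie-chart slice. One conflicting vote is recorded per tree (its
lexicographically smallest conflicting side, for determinism) and the
modal vote is reported as the top alternative. Unlabelled internal
branches are treated as fully supported so plain simulated topologies can
be scored. Root-adjacent splits, which are trivial in the unrooted sense,
are not assessable branches. The whole computation is checked against an
exhaustive pure-set-logic enumeration on 200 random 8-taxon tree sets.

Taxon-removal profiling re-runs the branch accounting with each taxon
pruned in turn and ranks taxa by total conflict reduction. A caveat
shown by simulation: conflict reduction is nearly symmetric between a
hybrid and its donor when the donor is a removable single taxon; the
ranking isolates the hybrid cleanly when the donor is an internal branch.

Quartet sampling draws, per branch and replicate, one taxon from each of
the four subtrees around the branch and scores the three quartet
topologies by JC69 likelihood (Felsenstein pruning on collapsed site
patterns; five branch lengths optimised by bounded coordinate descent,
three passes, tolerance 1e−4, branch lengths in [1e−8, 10]). A replicate
is informative when the best topology leads by at least ΔlnL = 2 (the
conventional threshold). Scores: QC = log3(3·t0/(t0+t1+t2)) clamped to
[−1, 1] (1 when no discordant replicate was seen), QD = 1 −
|t1−t2|/(t1+t2) (undefined when t1+t2 = 0, printed "–"), QI =
informative fraction. Numerical identity with the original
quartet-sampling tool is not claimed — that tool's likelihood engine and
exact score variants differ — but the documented anchor behaviors hold:
full support prints 1/–/1; a single dominant alternative gives QD = 0; a
near-zero internal branch gives |QC| ≤ 0.15 (typically via QI ≈ 0, since
no quartet clears the likelihood margin). Because replicates redraw from
small subsets, identical quartets recur and their evaluations are
memoised; this changes nothing statistically.

A practical saturation note: quartet paths beyond ~2 substitutions/site
leave essentially no signal, and replicates become uninformative rather
than wrong — visible in QI, not QC.

## Duplications and Ks

Rooted ingroup clades are extracted from supported homolog trees by
rooting at an outgroup tip and taking maximal outgroup-free clades with
mean internal support ≥ 50 and ≥ `min_taxa` taxa. A clade node whose two
daughters share ≥ 2 taxa is a duplication event, mapped to the MRCA of
the node's full taxon set on the species tree. On lossless simulations
this mapping is exact for internal branches (and terminal-branch events
are structurally undetectable, as noted above). Per-branch percentages
divide event counts by the number of extracted clades containing at
least two descendants of that branch — an explicit denominator choice;
zero-denominator branches report NA.

Ks uses NG86 with Jukes–Cantor correction: per-codon synonymous site
fractions from the standard code (changes to stop codons count as
nonsynonymous; stop and ambiguous codons are skipped), differences
averaged over all minimal mutation paths that avoid stop codons (a codon
pair whose every path is blocked is skipped), pS = Sd/S, Ks =
−(3/4)ln(1 − 4pS/3), saturation at pS ≥ 3/4. An ML codon-model estimator
was not used: NG86 admits a brute-force path-enumeration oracle, which
the tests run on 50 random codon-pair fixtures.

Per-taxon Ks distributions take every within-taxon pair co-occurring in a
cluster, excluding saturated pairs and values outside (1e−4, 3.0] — the
lower bound removes identical/allelic pairs, the upper bound matches the
usual plotting range. Mixtures are fitted on ln(Ks) by a 1-D Gaussian EM
(k = 1..k_max, 10 seeded restarts each, 300 iterations, tolerance 1e−8,
variance floor 1e−8), selecting k by BIC with 3k−1 parameters. The EM is
authored here because the per-iteration log-likelihood trajectory is
asserted non-decreasing on every fit; scikit-learn's GaussianMixture is
the independent cross-check in the tests. Fits refuse fewer than 50
values. Parameter recovery on the two-component benchmark (peaks 0.2 and
1.9, σ = 0.3, n = 4000) selects k = 2 with peak errors within 15%.

## Triplet introgression tests

For an ordered triplet (H, P1, P2), rooted-triplet topologies are tallied
across single-copy gene trees: n1 = species-concordant, n2 = H grouped
with P2 (the candidate introgression), n3 = the remainder. When H is the
species-triplet outlier the literal ((H,P1),P2) slot cannot be
concordant; the package keeps "n1 = concordant" as the invariant and
orients P1 as H's species sister whenever possible. Counting is a single
O(n²) pair-MRCA-depth sweep per tree; taxa with multiple tips are
excluded.

Under ILS alone the two minor topologies are equifrequent, so the null
test is an exact two-sided binomial on (n2, n3) — valid at small counts
where χ² is not. The inheritance probability is γ̂ = (n2 − n3)/(n1 + n2 −
2n3), clipped to [0, 1]; from p1 − p3 = (1−γ)(1−e^(−tA)) and p2 − p3 =
γ(1−e^(−tB)) it is exactly unbiased when the two parental internal
branches are equal and biased otherwise — every estimate carries that
caveat. A non-positive denominator (n1 not the majority) is reported NA.
The full scan tests all triples in all three hybrid-role directions
(3·C(n,3) rows) with a Bonferroni threshold of α divided by the number
of tests with γ̂_raw strictly inside (0, 1). Simulations at γ = 0.3
(tA = tB = 1, 2000 trees × 20 seeds) recover the mean within ±0.05, and
100 null datasets keep the family-wise false-positive rate at or below
the nominal 0.05. The three role assignments of one triple share the
same binomial p-value by symmetry; only the role with γ̂_raw ∈ (0, 1) can
be flagged significant, which is what identifies the hybrid.

This stage answers the same question as site-pattern and network-ML
methods — which lineages exchanged genes, and with what γ — but from
gene-tree triplet asymmetry; numerical agreement with those methods'
published estimates is not expected, and direction-of-flow concordance is
the meaningful comparison.

## Pipeline

One master seed drives everything; per-stage seeds are CRC32-derived from
the stage name, so identical configs reproduce identical outputs. The
default thresholds are the 24-taxon-scale values listed in `RunConfig`;
`RunConfig.toy()` is the scaled profile for ~8-taxon simulations
(occupancy 6/8, ortholog length 200, bootstrap 50, sequence scale 0.05
substitutions/site per coalescent unit so that speciation branches stay
below the deep-paralog cutoff). Manifest counts are monotone through the
filter stages, which the tests assert.

## Problem sizes used in the checks

The bundled verification runs use: 200 random 8-taxon gene-tree sets for
the concordance oracle; 500 lossless families for the MO and mapping
guarantees; 100 additive 8-taxon matrices for NJ; 20,000 coalescent
trees for the triplet closed form; 20 × 2000 trees for γ recovery and
100 × 1000-tree null datasets for error control; 50 NG86 fixtures and
n = 4000 for the mixture benchmark; 1000 quartet replicates per branch.
These sizes put Monte-Carlo error well inside the stated tolerances
while keeping the whole verification under a few minutes on one core.

## Known limitations

* No ILS in the duplication/loss generator and no duplication in the MSC
  generator — by design, so truths stay unambiguous; real gene families
  experience both at once.
* JC-only quartet likelihoods and NJ gene trees underfit real sequence
  heterogeneity; supply externally estimated trees where that matters.
* The γ estimator's unbiasedness requires equal parental internal
  branches; the package prints the caveat but cannot correct the bias
  without knowing the branch lengths.
* The duplication-percentage denominator is this package's explicit
  definition; other mapping pipelines may normalise differently, so
  absolute percentages are comparable only within a run.
* Terminal-branch duplications cannot be detected by the overlap rule at
  all; Ks distributions are the complementary signal for those.
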