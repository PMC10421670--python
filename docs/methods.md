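# Methods

## The inference problem

Roughly half the species in genera like *Nicotiana* are allotetraploids:
each carries two diverged subgenomes contributed by different diploid
ancestors through hybridization plus genome doubling. Given per-species
transcriptome-derived CDS sets grouped into orthogroups, the package
answers three questions per polyploid: which two diploid lineages are
closest to its progenitors, which of them was the maternal donor, and how
long ago the subgenomes diverged from those extant relatives. Around this
sit the standard phylogenomic diagnostics — gene-tree/species-tree
conflict, quartet support, cytonuclear discordance — that separate
hybridization from incomplete lineage sorting (ILS) and detect organelle
capture.

## Generative model (simulator)

The simulator defines the conditions under which every downstream claim is
tested.

**Species network.** A rooted, ultrametric backbone species tree with node
ages in Ma, plus hybrid events `(polyploid, maternal branch, paternal
branch, T_h, gamma, plastid donor)`. A parent branch is named by a tip
(`attenuata`) or a clade (`paniculata+knightiana` = the branch subtending
their MRCA, for ancestral/extinct donors). Validation enforces: tip ages
0, ages strictly decreasing toward the tips, each polyploid in exactly one
event, `T_h` inside the lifetime of every named parent branch (hence
younger than the parents' divergence), gamma in (0,1). Gamma is recorded
for provenance only — with exactly two homeologs per tetraploid the
inheritance proportion does not enter the sampling model.

**Coalescent.** Gene trees follow the multispecies coalescent: one
population per species-tree branch; within a branch, k lineages coalesce
at rate k(k−1)/2 × 1/g, where **g is the expected within-population
pairwise coalescence time in Ma** (larger g = more ILS). This single
intensity parameter replaces Ne-and-generation-time bookkeeping; the
closed-form checks only need t/g. The engine is msprime with `ploidy=1`
and `population_size=g` (verified: mean pairwise coalescence time = g).
Each diploid contributes one haplotype per locus (one transcript per
gene); each tetraploid contributes two homeologous haplotypes, modelled as
two extra populations that transfer their lineage into the maternal and
paternal parent branch at `T_h` (mass migration, so the receiving branch
remains active for its own sample). Homeologs never coalesce with each
other inside the polyploid.

**Sequences.** Strict clock at rate r substitutions/site/Ma, HKY(κ, π)
with optional Γ(α) site-rate heterogeneity, vectorised over sites via the
symmetrised eigendecomposition of the normalised rate matrix (checked
against `scipy.linalg.expm`). α = None (or 0 in the pipeline config)
means no heterogeneity, the α → ∞ limit. Alignments are gap-free by
construction; no indel model (a non-goal).

**Dataset emission.** Per locus: optional whole-taxon loss
(probability `loss_prob`), optional duplication (`dup_prob`: one extra
copy grafted onto a terminal branch, diverging an extra Exponential(mean
0.1 g) Ma — only there to exercise the copy-number filters). Homeolog
copies are written under opaque labels `h1`/`h2` whose maternal/paternal
identity is randomised per taxon and recorded in the truth record, so
headers leak no truth. The plastid locus is a single alignment simulated
with g/2 (organellar effective size) in which each polyploid contributes
one lineage entering its plastid-donor branch — the maternal parent by
default, or any other branch to emulate organelle capture. The
`TruthRecord` (JSON, stable key order) carries the config echo, events,
copy assignments, all gene trees and the plastid gene tree; every
acceptance check can be re-derived from it without rerunning.

**Randomness.** One master seed; per-locus substreams are spawned
deterministically (`numpy.random.SeedSequence`), so individual loci are
reproducible and full outputs are byte-identical across runs.

**Preset conditions.** The `nicotiana-like` preset is an 8-diploid +
outgroup backbone with crown age 9.24 Ma and root 30.4 Ma (the dated
backbone of the study system), carrying a young tetraploid
(sylvestris × tomentosiformis, T_h = 0.5 Ma) and an older one
(attenuata × undulata, T_h = 3.7 Ma). `rusticae-like` exercises a
clade-level maternal parent; `organelle-capture` donates the plastid from
a non-parent. Defaults r = 0.005 subs/site/Ma (a plant nuclear-gene scale
that puts ~30% divergence between ingroup and outgroup, matching the
observed variable-site fractions), g = 0.5 Ma (moderate ILS: t/g ≥ 2 on
every internal backbone branch), κ = 2, uniform base frequencies. The
paper trail gives no ILS magnitude for the real genus; g is our choice
and is stated wherever a result depends on it.

## Filtering and supermatrix statistics

The four low-copy criteria are applied in printed order with strict
inequalities (< 5 copies per taxon, < 3 per diploid, > 300 bp, ≥ 50%
ingroup coverage); a rejected orthogroup is attributed to the first
criterion it fails. The length criterion drops offending sequences rather
than whole orthogroups, then coverage is re-evaluated — the source
protocol is silent here and this choice preserves maximal data. Coverage
is computed over ingroup taxa only; outgroup presence is tracked
separately. Alignment trimming is a per-column gap+N fraction filter
(default 0.5) standing in for codon-aware trimmers; simulated loci are
gap-free, so it is exercised by constructed cases. A column is variable if
it has ≥ 2 distinct non-gap/non-N states and parsimony-informative if ≥ 2
states occur in ≥ 2 rows each; missing counts gap and N cells over all
cells.

## Tree methods

* **NJ + K2P.** Distances use pairwise deletion (transcriptome data are
  missing-prone); saturated pairs (non-positive log argument) are flagged
  and refuse tree building rather than silently truncating. NJ is
  dendropy's implementation behind the package interface; negative length
  estimates are clamped to 0. On additive matrices recovery is exact.
* **Bootstrap.** Site resampling; support = % of replicates containing
  each point-estimate bipartition, stored as 0–100 integer labels
  (posterior-style labels in [0,1] are rescaled ×100 on input). The
  NJ+K2P path precomputes per-pair site categories and draws multinomial
  column weights, so 1000 replicates on a supermatrix are cheap. Support
  labels are keyed to bipartitions and re-attached after any rerooting
  (node labels alone do not survive rerooting).
* **Rooting.** Outgroup rooting places the root mid-edge on the split
  separating the outgroup; MAD rooting minimises the root-mean-square
  relative ancestor deviation over all tip pairs, with the per-edge
  optimal position in closed form and ties broken by the
  lexicographically smallest bipartition. MAD is verified against an
  independent fine-grid search (the deviation of a pair (i,j) from a
  candidate root point reduces to |d_i − d_j| / d_ij).
* **Likelihood engine.** Felsenstein pruning over compressed site
  patterns, JC or HKY, branch lengths by coordinate ascent (bounded
  scalar minimisation per edge, convergence when a full pass improves
  lnL by < 1e−6). Topology search is deliberately omitted: topologies
  come from NJ or are supplied. Two-taxon JC fits match the closed-form
  MLE; lnL is rerooting-invariant (reversibility).

## Conflict accounting

* **Concordance pies.** Gene trees are rooted (outgroup when present,
  MAD otherwise) and branches below 33% support collapsed. For each
  species-tree clade restricted to a gene tree's taxa: concordant if
  present as a clade; conflicting if some gene-tree clade fails the
  four-quadrant compatibility test — computed with a virtual root taxon
  appended, because rooted-clade conflict on k taxa is unrooted-split
  conflict on k+1; otherwise uninformative. The dominant alternative
  counts each conflicting tree's smallest conflicting clade (ties:
  lexicographic). Verified against an exhaustive split-pair oracle.
* **Quartet sampling.** Per internal branch and replicate, one tip is
  drawn per incident subtree, the three quartet topologies are fitted by
  ML on the columns shared by the four tips, and the replicate counts
  toward its best topology iff ΔlnL ≥ 2 (JC by default — the speed choice;
  HKY available). QC = sign(t0 − max(t1,t2)) × (1 + Σ p_i log₃ p_i);
  QD = 1 − |t1−t2|/(t1+t2), undefined when t1+t2 = 0;
  QI = (t0+t1+t2)/n; QF per tip = fraction of its informative replicates
  that were concordant. Boundary behaviour is pinned by tests: equal
  counts → QC = 0; t1 = t2 = 0 < t0 → QC = 1 with QD undefined ("1/-/1",
  full support); no informative replicates → QI = 0, QC and QD undefined.
  Branches with a data-less subtree are skipped and reported.
* **Triplet skew test.** Under pure ILS the two minor rooted-triplet
  topologies are exchangeable, each with expectation (1/3)e^(−t/g); the
  test is χ² = (m₁−m₂)²/(m₁+m₂) on 1 df (no continuity correction), with
  the implied internal branch t̂ = −g ln(1.5 (m₁+m₂)/total). Significant
  skew favours introgression over ILS. Type-I error is calibrated by
  simulation (0.05 ± 0.02 at t/g = 1). Trees entering this test are
  collapsed at the separate 30% threshold kept as its own config key
  (`network_bs_threshold`), mirroring the distinct threshold used by
  network inference.
* **Cytonuclear conflicts.** Splits present in one tree and incompatible
  with the other, plus per-taxon sister groups in each — the tanglegram
  signal used to call hybrid origins (nuclear sister ≠ plastid sister)
  and organelle capture.

## Parentage and subgenome assignment

The similarity scorer is an explicit deterministic global alignment
(match +1, mismatch −1, gap open −2, extend −0.5, via
Bio.Align.PairwiseAligner): default-parameter BLAST is
environment-dependent, and a fixed in-repo scorer makes best hits exactly
reproducible. Exact cross-diploid ties credit nobody. The parent pair is
the top-count diploid plus the top diploid outside its local clade (the
smallest clade of ≥ 2 taxa containing it, configurable), formalising the
"read the two peaks off the heatmap" step; clade-level candidates pool
member counts. A row concentrated on one diploid (others ≤ 5% of the
maximum) raises an autopolyploid-like warning. Orientation: the maternal
parent is the pair member containing (or contained in) the polyploid's
plastid sister; if neither qualifies the orientation stays undetermined
and the plastid sister is reported as a capture candidate — never silently
forced. Assignment labels each polyploid sequence by the lineage of its
best hit; within an orthogroup two same-lineage copies keep only the
higher-scoring one; ambiguous sequences are discarded downstream. The
subgenome phylogeny concatenates diploids plus `P#maternal`/`P#paternal`
pseudo-taxa (≥ 10 classified loci each, otherwise excluded with a
warning) and is built by bootstrap NJ(K2P).

## Strict-clock dating

Node heights x (substitution units) minimise Σ over branches of
(observed length − (x_parent − x_child))² with tips at 0 and parent ≥
child (box-constrained linear least squares; an SLSQP fallback enforces
ordering in strongly anticlocklike cases). When the root has exactly two
children the two root-child branches are fitted as a single combined
residual: they are one unrooted edge whose split by the rooting is
arbitrary, and fitting them separately biases the root height toward the
midpoint (observed as ~5% age shrinkage before the fix). The calibration
is applied as a point value — r̂ = x_cal / age_cal, ages = x / r̂ — so the
fit is exact (RSS 0) on clocklike input, scale-equivariant (doubling the
calibration doubles every age), and ultrametric by construction.
Bayesian machinery (tree priors, MCMC, HPD intervals) is deliberately
replaced by this deterministic desk-scale estimator; uncertainty, when
needed, comes from redating bootstrap trees.

A hybridization date is the age of MRCA(pseudo-taxon, extant parent
lineage). It is an **upper bound** on T_h: the homeolog and the sampled
relative diverged when the homeolog's lineage coalesced inside the parent
branch, on average g Ma before the hybridization. Maternal and paternal
dates are independent numbers and are reported without averaging.

## Numerical and design choices

* Ties everywhere break lexicographically on taxon names; dominant
  alternatives by count then lexicographic split.
* Newick serialisation is canonical (children ordered by smallest
  descendant leaf) at 10 significant digits — beyond biological meaning,
  but coarse enough to absorb last-ulp summation-order differences in
  upstream libraries, keeping artifacts byte-identical.
* Quartet fits loosen the optimizer (lnL tolerance 1e−4) since only a
  ΔlnL ≥ 2 decision is consumed.
* Per-stage pipeline seeds are derived from the run seed and the stage
  name, so stage subsets reproduce full-run results.
* K2P saturation: the flag fires when 1−2P−Q ≤ 0 or 1−2Q ≤ 0 (or no
  shared sites).

## What the tests show — and what they do not

All validation is against the simulator, whose conditions are idealised:
a strict clock, no indels or alignment error, no assembly artifacts, no
lineage rate variation, gene flow only through the declared allopolyploid
events, and one haplotype per diploid. Passing tests therefore establish
that the algorithms are correct and calibrated under the stated model —
recovery of parent pairs, orientation and hybridization times on data
where the truth is known — not that real transcriptome data satisfy that
model. Two caveats found during development are worth keeping in mind for
real data: (1) best-hit subgenome classification conditions on the hit
being right, so at weakly informative loci it preferentially retains
low-divergence copies and can bias concatenated divergence (hence dates)
slightly downward; the effect vanishes when loci are informative enough
that classification is essentially error-free. (2) Dates inherit the
within-branch coalescent offset (+g on average) and are upper bounds on
the hybridization time, not estimates of it.

Problem sizes used by the shipped checks (chosen as desk-scale
replicates of the study design): 10,000 loci for the closed-form
concordance calibration; 1,000 simulated datasets for the triplet test's
type-I error; 10 seeds × 300 loci × 500 bp on the 8-diploid +
2-tetraploid network for parentage recovery; 5 seeds × 100 loci for
dating recovery; the bundled end-to-end preset runs 40 loci × 400 bp.
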