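# Methods

`clonedeconv` reconstructs the subclonal architecture of a tumor from
multi-region sequencing of a single patient: several biopsies of the primary
tumor plus (typically) one lymph-node metastasis, each with matched-normal
(blood) sequencing, profiled twice — an exome-wide discovery run at moderate
depth and an ultra-deep targeted validation run over the discovered sites.
This note records the model, its assumptions, the tunable parameters, and
what the synthetic validation does and does not demonstrate.

## Somatic variant selection

A site's B-allele frequency (BAF) in a sample is `alt / (ref + alt)`;
zero-depth records are *undefined* (NaN), never 0. Two stages:

* **Discovery** (exome depth): call a site somatic when some biopsy shows
  BAF ≥ 5% with ≥ 3 alternative reads, and blood has ≥ 10× depth with 0
  alternative reads. The criteria are deliberately loose (sensitivity over
  specificity); the deep validation pass is what removes false positives.
* **Validation** (ultra-deep): call when some biopsy shows BAF ≥ 3% with
  ≥ 10 alternative reads and blood has ≥ 50× depth with BAF ≤ 1%. Once a
  site is called anywhere, its *presence* in the other biopsies is granted
  down to arbitrarily low BAF provided at least `secondary_min_alt`
  (default 5) alternative reads support it — deep coverage makes a handful
  of alternative reads meaningful even below the calling threshold.

All thresholds are inclusive, and BAF thresholds are compared by integer
cross-multiplication (the threshold held as an exact rational), so a biopsy
at exactly 3/60 = 5% is called and no binary-float rounding can flip a
boundary count. Zero-depth biopsy records count as "no data", never as
evidence against a call; a missing blood record is an error because somatic
status cannot be certified without it. Patients are filtered independently;
a site failing blood criteria in one patient is not suppressed in another
(configurable via a site blocklist, which also serves for known-polymorphism
pre-filtering without bundling any database).

The confirmation rate is |validated| / |discovery| over site keys.

## Copy number

Windows are defined on the normal sample: each window spans a fixed count of
consecutive normal reads (default 10,000), so the normal denominator is
constant by construction and window width adapts to capture density. Reads
are assigned to windows by index in the per-chromosome sorted read list;
window bounds are the first/last member read positions (1-based inclusive).

    LogR = log2( (tumor_reads / normal_reads) / s ),

with `s` the library-size factor (total tumor / total normal reads),
followed by per-sample median centering so the modal diploid state sits at
LogR 0. Median centering is our normalization choice: most of the genome is
copy-neutral in these tumors, so the median window is diploid. Zero-read
tumor windows are floored at a 0.5-read pseudo-count and flagged. Each
mutation inherits the LogR of its containing window (positions in
inter-window gaps or past the final window take the nearest window's value,
flagged `nearest`) — a neighborhood mean, not a per-base estimate.

Segmentation and allele-specific ploidy solving are out of scope; windows
feed the per-mutation copy-state assignment only.

## The locus model

A biopsy with purity ρ mixes normal diploid cells with cancer cells. A
mutation carried by fraction `f` of the cancer cells sits in one of four
allele configurations in its carriers (m mutant copies of n total):

| state | m | n | meaning |
|-------|---|---|---------|
| AB    | 1 | 2 | heterozygous diploid |
| B     | 1 | 1 | LOH — wild-type allele lost |
| BB    | 2 | 2 | copy-neutral LOH — wild-type lost, mutant duplicated |
| ABB   | 2 | 3 | mutant duplicated, wild-type retained |

Non-carrier cancer cells are assumed diploid at the locus (copy events ride
with the mutant lineage). Then

    BAF(state, ρ, f)  = ρ·f·m / ( ρ·(f·n + (1−f)·2) + 2·(1−ρ) )
    LogR(state, ρ, f) = log2( ( ρ·(f·n + (1−f)·2) + 2·(1−ρ) ) / 2 )

Each mutation is assigned the (state, f) candidate minimizing
tolerance-scaled squared distance to its observed (BAF, LogR), with f drawn
from the fitted clone fractions plus 1. A candidate is admissible when
|ΔBAF| ≤ τ_BAF (default 0.08) and |ΔLogR| ≤ τ_LogR (default 0.4) — roughly
half the gap between adjacent state expectations at ρ = 0.5; inadmissible
points stay `unassigned` rather than being forced. Ties break toward the
state with fewer copy-number changes from AB, and f within 0.05 of 1 counts
as clonal (fitted fractions carry sampling noise).

**Known degeneracy.** BB at fraction f and AB at fraction 2f predict the
identical point (ρ·f, 0): a subclonal copy-neutral LOH over half the cells
is indistinguishable from a clonal heterozygous mutation on (BAF, LogR)
alone. When both fractions are offered the tie-break picks the simpler AB.
Similarly, a truncal mutation whose wild-type allele is lost in only a
*sub*-lineage is a mixture of AB and B carriers and lands between the two
state expectations; it is assigned whichever is nearer (usually AB until
the event lineage dominates a biopsy). Such ambiguity is reported, not
resolved.

## Purity

Purity is taken as provided when known (e.g. from pathology); otherwise it
is estimated per biopsy as twice the kernel-density mode of the clonal
cluster's AB BAFs (a clonal AB mutation has expected BAF ρ/2), capped at 1
and requiring ≥ 5 mutations. This is a pragmatic stand-in estimator — it is
labelled as such in its output — and purity feeds only the copy-state
assignment; clustering and clone fractions are purity-free (ρ cancels in
the BAF ratio).

## Clustering mutations into clones

Mutations in the AB state carry the clean clone signal: expected BAF in
biopsy b is ρ_b·φ_kb/2 for a clone with carrying fraction φ_kb. The
pipeline first screens for AB by LogR (a mutation enters clustering only if
|LogR| ≤ `ab_logr_tol` = 0.15 in every biopsy; window noise at 10,000 reads
has SD ≈ 0.02, so the screen is ~7σ wide), then fits a finite binomial
mixture over biopsies:

    alt_ib ~ Binomial(depth_ib, θ_kb)   for mutation i in cluster k,

by EM for K = 1..K_max (default 8–9), with deterministic initialization
(k-means on BAF vectors at a fixed seed) and K selected by BIC with
K·B + K − 1 free parameters. Mutations are hard-assigned by maximum
responsibility; non-convergence keeps the best iterate with a warning.
Mutations screened out as non-AB are attached afterwards to the nearest
cluster in presence-pattern space (binary presence at ≥ 5 alt reads,
Hamming distance, BAF distance as tie-break) so copy-shifted mutations
still carry cluster labels for reporting. Replacing the original study
style of visual plot interpretation with this reproducible EM procedure is
the central design decision of the package.

Per-biopsy clone fractions are the BAF ratio

    φ_kb = mean AB-BAF of cluster k in b / mean AB-BAF of the clonal cluster in b,

clipped to [0, 1], where the cluster means are depth-weighted
(pooled alt / pooled depth over members) and the clonal cluster is the one
whose mean BAF is maximal in every biopsy, within a noise tolerance
(max(2%, 0.02) absolute); if no cluster dominates everywhere the
largest-BAF-sum cluster is used and flagged.

## Clone tree

Under the inheritance assumption — every clone carries all of its
ancestors' somatic mutations — cumulative fractions obey, in every biopsy:
a clone never exceeds an ancestor, and sibling subclones sum to at most
their parent (pigeonhole). `build_tree` declares A an ancestor of B iff
φ(A,·) ≥ φ(B,·) − ε everywhere and B is present (φ > ε) only where A is;
each cluster's parent is its minimal ancestor, clusters with none hang off
a virtual root. Among multiple minimal ancestors the most prevalent one
(largest φ sum) is chosen, ties by id, and the ambiguity is recorded
(e.g. a clone detectable in one biopsy where two candidate parents are
equally prevalent genuinely cannot be placed). ε defaults to 0.1 absolute,
matching the fraction-recovery tolerance at deep coverage. The constructed
tree is re-validated; a pigeonhole violation raises an error carrying the
offending (biopsy, clusters, fractions) certificate. Clusters below
`min_cluster_mutations` (default 5) are excluded from construction and
listed separately — too few mutations to place with confidence.

The pie-chart view (exclusive fraction) is φ(c) minus the summed φ of c's
children, floored at 0, with the residual to 1 labelled
`normal_or_unexplained`.

**Metastatic pattern.** With biopsy roles known, the node/primary-shared
clones are examined: if they form a single ancestral chain the node is
*monoclonally seeded*; if they contain ancestrally unrelated lineages,
*polyclonal seeding*. Independently, a node-private and a primary-private
clone sharing a parent indicates *parallel* subclone birth on both sides.
Multiple labels can apply simultaneously, so the classification returns a
list.

## Cohort reports

* **Venn counts**: a validated mutation counts as present in a biopsy only
  with ≥ 5 alternative reads there; every mutation falls in exactly one
  biopsy-subset cell (below-threshold-everywhere mutations land in the
  empty cell, so cells always partition the validated set). Biopsies with
  no data (or no tumor content) can be excluded from the diagram.
* **Selection test**: under neutral mutagenesis roughly 2 of 3 point
  mutations are nonsynonymous, so the observed nonsynonymous count among
  (missense + stopgain + stoploss + synonymous) point mutations is tested
  one-sided against Binomial(n, 2/3) with an exact tail; indels and splice
  variants are excluded from the test (their neutral expectation is not
  2:1). The one-sided exact binomial is our formalization of "exceeds the
  2:1 ratio"; a chi-square alternative sits behind a flag. The default
  pools mutations cohort-wide; per-patient testing is a mode.
* **Driver evidence**: per-gene boolean flags — recurrence (≥ 2 patients),
  loss-of-function (stopgain/frameshift/splice), LOH (any member mutation
  in state B/BB in any biopsy), bi-allelic (≥ 2 independent hits in one
  patient: two mutations, or mutation + LOH over it) — ranked by flag
  count. External columns (driver scores, database frequencies, survival
  hazard ratios) are merged verbatim from input tables, never computed.

## The simulator

`simulate` draws synthetic cohorts matching the targeted study design:
3 primary-region biopsies + 1 node, purity 0.2–0.8, exome depth 95×,
validation depth 1693×, tens to ~150 somatic mutations per patient, 1–3
prominent clones per biopsy, and clone-private regional copy events.
Observed counts are depth ~ Poisson(mean depth) and
alt ~ Binomial(depth, true BAF), with true BAF from the locus model above
(generalized to carriers split across copy states when an event covers only
a sub-lineage). Blood draws alt ~ Binomial(depth, 0.001) at somatic sites —
below the 1% blood-BAF validation ceiling, so filter tests can exercise
that boundary. Germline heterozygous SNPs (BAF 0.5 everywhere, blood
included) are emitted alongside; window tables are emitted pre-binned with
tumor counts scaled by (ρ·n̄ + 2(1−ρ))/2 plus Poisson noise. The exome and
deep runs share true BAFs, as when a validation assay re-measures the same
positions. The clone-fraction matrix is stored cumulatively (clone +
descendants); scenario validation enforces the root-at-1, child-below-
parent and sibling-sum invariants, and that copy events on one chromosome
live in nested-or-disjoint lineages.

`scenario_like_patient1` encodes a 7-clone, 4-biopsy scenario with a
branching second-generation clone (three daughters: one primary-shared,
one node-private with its own daughter, one back-private), independent LOH
over the same truncal mutation in two disjoint sub-lineages, a truncal
stopgain with node-restricted LOH, and a clonal LOH — exercising every
downstream feature at once. The back-biopsy fractions
(2a 0.62 / 2b 0.38 / 3c 0.38) keep the generating tree the unique
consistent one while preserving the reported 2a-vs-2b placement ambiguity
for the back-private clone.

`random_scenario` draws random identifiable scenarios for recovery studies:
random rooted trees, 1–3 prominent clones per biopsy with coarse exclusive
occupancies, purity uniform in [0.2, 0.8], rejection-sampled until every
clone is detectable somewhere, every cluster pair is ≥ 5 binomial SDs apart
in some biopsy at the target depth, and the fraction matrix pins down a
unique tree under ε = 0.1.

**What the simulator does not emulate**: sequencing error inside tumor
samples (alt counts are exact binomial draws from the true BAF), mapping
artifacts and strand bias, overdispersion beyond Poisson/binomial,
germline copy-number variation, focal events smaller than a simulated
chromosome, and mutation-rate heterogeneity along the genome. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to real-data artifacts.

## Validation scale and numerical choices

The validation suite runs: an exhaustive filter-rule sweep over ~1.4M
boundary-straddling count tables against a literal transcription of the
rules; the 24-point noise-free state-assignment grid; 100 seeded recovery
simulations (3–7 clones, 20 mutations/clone, depth 1693×) for cluster
count, fraction error and tree topology, with brute-force tree enumeration
as the oracle for ≤ 6 clusters; the end-to-end 7-clone integration run; an
exact-integer-arithmetic check of the binomial tail up to n = 500; and the
closed-form LogR limit log2(1 − ρf/2) for a one-copy loss on a (ρ, f)
grid. At these scales the fraction estimator's irreducible sampling SD is
~0.02 near φ = 1 at the lowest purity, which is why the recovery band is
±0.05. EM success probabilities are floored at 1e-6 (θ) and 1e-12 (π);
EM stops at a 1e-8 relative log-likelihood change or 500 iterations.

Problem sizes throughout (25 windows/chromosome, 8 neutral chromosomes,
~150 mutations/patient, 100 replicates) are chosen to make the full
validation reproducible on a laptop in a few minutes.
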