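# Methods

## Overview

`crossmr` implements a cross-species master-regulator (MR) discovery
pipeline: ranked differential-expression signatures per species → regulon
enrichment ("MR activity") against each signature → Stouffer integration of
the two species' MR lists → survival-based prioritization of the conserved
MRs in a patient cohort, with an empirical random-MR-set specificity null.
This note records the model assumptions, the numerical conventions, and the
design decisions taken where the procedure was genuinely open.

## Signatures

Differential signatures use the two-sample two-tailed Welch *t*-statistic
(unequal variances), signed so that positive scores mark genes up in the
second group. Each group must contribute at least 5 samples (default
`min_n=5`); the statistic is too unstable below that. Genes with zero
variance in both groups are dropped with a warning: when the means are also
equal the statistic is 0/0, and when they differ it is infinite — neither
belongs in a finite ranking. All rankings order descending by score with
ties broken lexicographically by gene id, so every ranking is total and
identical across platforms.

Per-patient activity requires a per-sample signature; the construction is a
design choice, since a two-group statistic does not apply to one sample. We
use the cohort z-score, z_ij = (x_ij − mean_i)/sd_i with the n−1 sd
denominator, the simplest convention that expresses "how far is this
patient's expression of gene *i* from the cohort". A median/MAD variant
would be more outlier-robust; the z-score was chosen for interpretability
and testability (per-gene mean 0, sd 1 across samples, exactly).

Humanization maps every source gene through the ortholog table; a target
gene hit by several sources keeps the score of largest absolute value (ties
resolve to the lexicographically smallest source), on the rationale that
the strongest differential evidence among co-orthologs should represent the
human gene. Unmapped genes are dropped and counted in the log.

## Enrichment statistics

The enrichment score is the classical weighted Kolmogorov–Smirnov running
sum over the ranking: hits add |score|^w normalized by the total hit
weight, misses subtract 1/(N−|S|); ES is the running-sum value of largest
magnitude (first occurrence on exact ties), and the query genes at or
before (ES > 0) / at or after (ES < 0) the extremum form the leading edge.
If every hit has exactly zero score under w > 0 the hit weights degenerate;
we fall back to unweighted increments rather than divide by zero.

Significance is by **gene permutation**: null query sets of identical size
drawn uniformly without replacement from the signature. NES is the
permutation z-score (ES − null mean)/null sd — this, not the
positive/negative-mean rescaling of some GSEA implementations, is what
makes large NES magnitudes attainable. Two-sided p-values use the add-one
rule (1 + #{|ES_null| ≥ |ES_obs|})/(n_perm + 1), so p is never 0 and never
below 1/(n_perm+1). Permutation nulls are computed by an O(k) candidate
evaluation per placement (the running sum is piecewise linear, so its
extrema lie at hit positions or immediately before them); a test pins this
fast path to the full running-sum scan.

Signature-versus-signature comparisons use two-tail GSEA: the query
signature's top-200 and bottom-200 genes (reduced with a warning when the
shared universe is small) are scored separately against the reference
restricted to the shared universe. The leading-edge overlap statistic
divides |A∩B| by the smaller set (configurable to the union — the choice of
denominator is a convention) and tests the 2×2 membership table over the
universe by chi-square without continuity correction. Pathway enrichment
applies the same permutation machinery to every set of a GMT collection,
skipping sets with fewer than 5 overlapping genes.

The weight exponent defaults to w = 1 for signature-level GSEA (the
standard weighted statistic) and to **w = 0 for regulon activity**: for a
regulon query the evidence is where the targets rank, and on t-statistic
signatures the score-weighted null is heavy-tailed — a handful of
large-|t| background genes dominate random placements, inflating the null
spread and compressing every NES toward zero. Both conventions are exposed
on every function (`weight_exponent`) and in the pipeline configuration
(`weight_exponent` for GSEA, `mr_weight_exponent` for activity).

## MR activity

A regulator's activity in a signature follows the two-tail regulon
convention: each negative (repressed) target's score is negated, the
signature is re-ranked, and the full target set is scored as one query. A
regulator whose positive targets are overexpressed and/or negative targets
underexpressed therefore scores positive (active); the converse scores
negative (repressed). The permutation null preserves each regulon's
(n_pos, n_neg) split: random target placements with random mode
assignments. Because an activity sign carries no meaning under the null,
NES is defined as ES/RMS(null) — the z-score against the sign-symmetrized
null, which is mean-zero by construction; p keeps the add-one two-sided
form on the drawn placements. Degenerate instances (regulon covering the
whole signature, zero-spread null) are flagged per row, never raised, so
one pathological regulon cannot abort a screen. An exhaustive-null mode
enumerates every placement on small universes and is pinned to a
brute-force oracle in the tests.

Note that swapping all modes of a regulon flips the sign of its activity
but does not negate the NES *exactly* in general: the adjustment negates
target scores only, so the adjusted ranking reflects exactly only when the
background score multiset is symmetric.

## Cross-species integration

Mouse regulator ids are translated through the ortholog map before
intersection (several mouse regulators collapsing onto one human id resolve
by max |NES|). Per common regulator, z_species = signed NES and
z_combined = (z_mouse + z_human)/√2 — equal species weights, as there is no
principled reason to trust one species' network more — with the two-sided
normal tail as combined p. Signed NES (rather than signed −log p) was
chosen as the Stouffer input because the NES is already on a z scale.
Conserved MRs default to p < 10⁻⁴, directional concordance required, and
activation (z > 0); all three are configurable. No multiple-testing
correction is applied beyond these fixed thresholds — the downstream
survival screen is the error control in practice — and this is deliberate.
An annotation filter reduces a conserved table to a user-supplied
regulator list (e.g., curated epigenetic regulators); the package does not
perform ontology discovery.

## Survival prioritization

The Cox screen fits one univariate proportional-hazards model per regulator
with continuous per-patient activity as the covariate (no clinical
covariate adjustment, matching the screening character of the step), and
reports the Wald z and p. It requires ≥ 20 matched samples and ≥ 5 events;
constant-activity and non-converged fits are flagged, never silently
dropped. Patients are stratified by Euclidean k-means (k = 2, best of 100
restarts) on the candidate-MR activity matrix; the cluster with the larger
mean activity is labeled "high". Group comparison is the standard two-group
log-rank test, with the hazard ratio (and 95% CI) from a proportional-
hazards fit on the group indicator. Time units pass through unchanged.

The specificity null re-runs the stratification for `n_iter` (default
1000) random regulator sets of the candidate size, recording the log-rank
p of each; the empirical p is
(1 + #{p_null ≤ p_observed})/(n_iter + 1) — "reached or outperformed" is
inclusive, and the add-one correction keeps the empirical p away from an
unreportable 0 (a plain fraction is available by post-processing the
retained null p-values, which are all written to JSON). The pool the
random sets are drawn from is a real modelling choice: drawing from *all*
tested regulators includes the candidates themselves, so roughly half of
random 8-sets from a 100-regulator pool contain at least one candidate and
the null is contaminated by the very signal under test. The pipeline
therefore excludes the candidate set from the pool (the question asked is
whether the candidates outperform random sets of *other* regulators); the
full-pool behaviour remains the library default of `random_set_null` and
the pool choice is logged in the run manifest. Exclusion carries its own
cost: when the pool is small relative to the set size, the null sets
overlap heavily with one another, their log-rank p-values cluster, and the
empirical p of a disjoint candidate set becomes anti-conservative (on
null cohorts with a 22-of-30 pool the fraction of empirical p ≤ 0.05 was
0.16, versus 0.04 for the full-pool default). Use exclusion only when the
pool is an order of magnitude larger than the candidate set, as in the
pipeline's default configuration (~92 non-candidates for sets of 8); at
small pools prefer the full-pool default and accept its conservatism.
Degenerate
iterations (no clustering split, no events) conservatively score p = 1 and
are counted. Null iterations use fewer k-means restarts (default 10) than
the observed stratification; the null compares *sets*, not optimizer luck,
and the reduced restarts are applied to every iteration identically.

## Synthetic study generator

The generator emulates the data shapes the real study consumes, with known
planted truth recorded before any noise is drawn:

- **Interactome**: 100 regulators with 20–60 targets drawn uniformly from
  a 2000-gene universe, mode +1 with probability 0.7, weight 1. The human
  interactome is the mouse network translated through the ortholog map.
- **Ortholog map**: every surviving mouse gene maps to a distinct human
  id; 5% of genes are dropped and 2% map to two human ids (exact rounded
  counts), emulating homology-table drop-outs and one-to-many entries.
- **Two-group cohorts** (8 samples/group): group A is baseline Gaussian
  noise (sd 1); group B adds mode·effect (default 1.0) on every target of
  every planted regulator, summed over planting. Effect 1.0 at n = 8/group
  puts targets at Welch |t| ≈ 2 — individually unremarkable, discoverable
  only collectively, which is the regime MR analysis addresses.
- **Survival cohort** (200 patients): one latent activity a ~ N(0,1) per
  patient shared by all 8 planted regulators (a coordinated program, as a
  conserved MR module would behave), expression shifted by mode·effect·a,
  event times exponential with rate 0.02·exp(0.8·a) censored at 120 time
  units (≈ 82% events at baseline).
- Planted regulators are drawn from regulators whose regulons survive
  ortholog translation: a cross-species study is only defined for
  regulators comparable in both species.

Everything derives from one integer seed through fixed per-stage
sub-seeding (`SeedSequence` spawn keys), so any stage regenerates
bit-identically in isolation and byte-identical file reruns are a tested
contract.

What the generator does **not** emulate: count-level noise
(negative-binomial overdispersion, library-size effects — the pipeline
consumes normalized values by design), batch effects, correlated
co-expression beyond the planted program, competing risks, and informative
censoring. Passing tests therefore demonstrate correctness and calibration
of the statistics under an additive Gaussian world, not robustness to
real-data pathologies.

## Numerical conventions and degenerate inputs

- Rankings: descending score, lexicographic gene-id tie-break; running-sum
  extremum: first occurrence on exact ties.
- Sample sd uses the n−1 denominator throughout.
- p-values from resampling always carry the add-one correction.
- Zero-variance genes, constant activity rows, non-converged Cox fits,
  degenerate regulon instances: flagged or dropped with a logged count,
  never silent.
- Zero-event cohorts raise a no-events error at every survival entry point.
- All file formats are plain TSV/JSON with full-precision floats; reruns
  are byte-identical.

## Problem sizes used by the test suite

Unit tests run on reduced synthetic studies (300 genes, 20 regulators,
6 samples/group, 60 patients). The end-to-end checks use the default study
conditions (2000 genes, 100 regulators, 1000 permutations, 5–20 seeds);
the nested empirical-p calibration uses 50 replicate cohorts at a reduced
scale (500 genes, 30-regulator pool, 60 patients, 50 activity
permutations, 200 null iterations), the package's own choice of a scale at
which the nested resampling remains a routine computation.

## Known limitations

- The per-sample z-score signature assumes the cohort is an appropriate
  reference; strong cohort composition effects (e.g., a cohort dominated
  by one subtype) shift every patient's activity.
- Gene-permutation nulls ignore inter-gene correlation; on real data the
  NES scale is optimistic relative to phenotype-permutation nulls. The
  calibration tests certify the gene-permutation convention only.
- Edge weights in interactomes are accepted and validated but the default
  analysis is unweighted; no published weighting convention was adopted.
- One-to-many ortholog resolution (max |score| / max |NES|) is a
  convention; alternatives (mean, first) are not exposed.
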