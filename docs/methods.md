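# Methods

This note documents the statistical procedures implemented in `txresponse`,
the defaults they ship with, the design choices that were genuinely open,
and what the synthetic-data tests do and do not demonstrate about real data.

## Normalization and paired fold changes

Counts are normalized by the trimmed mean of M-values (TMM). The reference
sample is the one whose upper-quartile count fraction is closest to the
cohort mean. For each sample against the reference, genes with a zero count
in either member of the pair are dropped; per-gene M (log2 expression ratio)
and A (average log2 abundance) values are doubly trimmed (30% of M, 5% of A,
both tails) and the scaling factor is the mean of the surviving M-values
weighted by the inverse asymptotic binomial variance. Factors are re-centered
to geometric mean 1, and expression is reported as
`log2(1e6 * count / (lib_size * factor) + prior)` with a pseudo-count
(`prior`) of 1 by default — the pseudo-count is configurable because its
value is a convention, not an estimate. The implementation reproduces the
edgeR reference factors to ~1e-10 on shared inputs (checked in the test
suite via Rscript).

One subtlety: the *weighted* trimmed mean is not exactly invariant to
rescaling one sample's counts by a constant (the rescaled sample's inverse
variance weights scale by 1/k while the reference's do not). The unweighted
variant (`weighted=False`) is exactly invariant; the weighted default is
invariant to ~1% at realistic depths. The weighted estimator is kept as
default because it is the field convention.

Batch centering fits, per gene, a least-squares model of expression on
preserved-group indicators plus sum-to-zero-coded batch indicators and
subtracts only the fitted batch component. Sum-to-zero coding makes the
removed component average to zero over a balanced design, so overall
expression level and group contrasts are preserved; batch labels perfectly
confounded with the preserved groups are rejected. The operation is
idempotent.

Paired fold changes are computed per OT sample against the mean of that
patient's PT profiles (patients with several PT biopsies are collapsed by
averaging — a choice, since nothing in the data dictates the collapse rule;
each OT biopsy keeps its own column because OT samples carry their own
response label). OT samples without a PT baseline, or with an unknown
response, are skipped with a warning rather than imputed.

## Differential statistics

The within-therapy responder contrast Δlog2FC is the difference of
arithmetic means of paired fold changes between responder and non-responder
pairs. Significance uses a two-sided two-sample t-test — Welch by default
(`equal_var=False`), since pair counts per group are usually unbalanced and
nothing guarantees equal variances; Student's variant is a switch. P-values
are BH-adjusted within one therapy's contrast (each therapy's DEG list is
defined independently). The DEG rule is the conjunction Δlog2FC ≥ 1 and
q < 0.05; down-regulated genes use the mirrored rule. Genes with fewer than
two finite fold changes in a group are dropped from testing; genes with zero
variance in both groups get p = 1 with a log note.

The cross-therapy statistic ΔΔFC = Δlog2FC_A − Δlog2FC_B is evaluated on
the shared gene universe with the conjunction ΔΔFC ≥ 1 and Δlog2FC_A ≥ 1
(symmetric for B). Group comparisons of scalar features use the two-sided
Wilcoxon rank-sum test: exact enumeration when both groups have < 8
observations and no cross-group ties, otherwise the normal approximation
with tie correction.

## Gene-set scoring

Single-sample scores use a rank-based weighted Kolmogorov–Smirnov running
sum: within a sample, genes are ranked by expression (average ranks at
ties); walking the list from the top, member genes step the running sum up
in proportion to rank^0.25 and non-members step it down uniformly; the score
is the sum of running-sum deviations. This replaces the kernel-CDF statistic
of the commonly used GSVA implementation deliberately: downstream the scores
are used only to rank and median-stratify samples, for which any monotone
single-sample enrichment score is sufficient, and the rank-sum form is
simple, exactly testable by hand, and invariant to monotone transforms of a
sample's expression. A mean-z alternative (per-gene z-score across samples,
averaged over members) is provided. Sets overlapping the expression matrix
by fewer than 3 genes are skipped — one or two genes is a marker lookup,
not an enrichment.

Cell-population abundance is the marker-mean estimator: the arithmetic mean
of log2-CPM values of a population's marker genes, comparable across samples
within a population. Marker lists are user-supplied GMT inputs; no
proprietary marker panels are bundled. Over-representation of a gene list
against a collection uses the one-sided Fisher exact test on the 2×2
membership table over a user-stated universe, BH-corrected across the
collection.

## Repertoire statistics

Clonotype records are filtered to productive sequences (flag set, no `*` or
`_` in the CDR3aa), then convergent clonotypes — identical amino-acid CDR3,
different nucleotide CDR3 — are merged per sample and chain with counts
summed; the representative nucleotide sequence is the highest-count member.
V-gene agreement is *not* required for convergent merging (the defining
property is amino-acid identity) but *is* required for lineage inference.

Diversity is count-weighted by default: pᵢ = countᵢ/Σcount, Shannon
H = −Σ pᵢ ln pᵢ in nats, normalized diversity (Pielou evenness) H/ln R for
richness R > 1, clonality 1 − H/ln R. A monoclonal repertoire is assigned
evenness 0 and clonality 1 (the 0/0 limit is resolved toward "maximally
clonal"). A clone-weighted variant (every clone weight 1) is available via
a flag. The "diversity" exposed to survival stratification is unnormalized
H, with richness and evenness also emitted.

Heavy-chain lineage inference partitions records by (V gene, J gene,
junction nucleotide length) and clusters each partition's CDR3nt sequences
by single linkage under normalized Hamming distance, cutting the dendrogram
at a threshold. Single linkage is chosen because SHM produces chains of
nearby variants: a descendant two substitutions from the founder may be one
substitution from a sibling. The automatic threshold pools every sequence's
nearest-neighbor distance within its partition, fits a Gaussian KDE
(Silverman bandwidth, 512-point grid), and takes the density minimum between
the two highest local maxima; with fewer than 20 distances or a unimodal
density it falls back to 0.1 normalized Hamming (the conventional default in
SHM clone grouping), logging which branch fired. SHM frequency is the
fraction of germline clones (clusters) containing ≥ 2 distinct nucleotide
sequences. Clone turnover between paired repertoires is the fraction of
post-treatment CDR3aa clones absent pre-treatment.

## Survival

Kaplan–Meier estimation and the (unweighted) log-rank test are delegated to
lifelines; the log-rank statistic was verified against R's `survdiff` on
shared inputs. Note the chi-square approximation is mildly liberal at
moderate sample sizes: at 50 subjects per arm with all events observed, the
empirical type-I error at α = 0.05 is ≈ 0.055–0.06 — a property of the
test, not of this implementation.

The Cox partial likelihood is maximized by Newton–Raphson written here
(rather than delegated) so that both Efron (default) and Breslow tie
corrections are available and the convergence rule is explicit: iterate to
max |score| < 1e-9 or 25 iterations, halving the step when it decreases the
likelihood beyond float noise; a stalled likelihood with |score| < 1e-6 is
accepted as converged. Coefficients beyond |β| > 20 abort with a separation
error suggesting penalization. Covariates are centered internally (β is
shift-invariant) for numerical stability. Wald statistics and fixed 95%
confidence intervals exp(β ± 1.96 se) are reported. The fit agrees with a
brute-force numerical maximization of an independently coded partial
likelihood to ~1e-7 and with lifelines to ~1e-6; at n = 300 with a true
log-HR of 0.7 and ~30% censoring the Wald interval's empirical coverage is
≈ 0.92 — the usual modest finite-sample undercoverage of Wald intervals.

Stratification follows "high: median and above, low: below median", with
the even-n median the midpoint of the two central order statistics.
All-identical values degenerate to all-"high" with a warning. The joint
2×2 analysis median-stratifies two features, runs a log-rank test across the
non-empty strata (identical features collapse the design to two groups), and
fits a Cox model on the two high-indicators and their product; the
interaction fit is skipped when an indicator is constant or collinear.
Progression-free-survival analyses can pre-filter to biopsies taken before
progression via a caller-supplied flag column.

## Synthetic cohorts

The expression generator emulates a two-therapy paired-biopsy cohort: gene
baselines are log-normal (σ = 1 on the natural-log scale), each patient
draws a per-gene baseline shift (σ = 0.5 log2 units, shared between that
patient's PT and OT samples, so it cancels in pairing but creates realistic
between-patient spread), counts are negative-binomial with variance
mean + φ·mean² (φ = 0.2, bulk-RNA-seq-like), library sizes are uniform on
0.8–1.2 million, and planted genes receive a 2^Δ multiplier on the mean
*only* in OT samples of responders of the designated therapy, so Δ is the
asymptotic Δlog2FC. Batch offsets are multiplicative on the mean (scalar
per batch, optionally with gene-level wobble). Defaults — 20 patients per
response arm per therapy, 2000 genes, 50 planted genes at Δ = 2 — are the
cohort conditions used throughout the recovery tests.

The repertoire generator draws germline clones with uniform V/J assignments
from pools of 10 and 4, in-frame junctions of 36–60 nt built from sense
codons, and Zipf(2) clone sizes. With probability ρ = 0.3 a clone spawns
2–4 descendants, each a per-base substitution copy (μ = 0.02) of the
germline junction at fixed length (no indels); substitution patterns that
would create a stop codon are resampled, mirroring the purging of
nonproductive variants. Ground truth stores each record's founder clone and
the realized fraction of multi-variant clones.

The survival generator draws exponential event times with rate
λ·exp(xβ) (λ = 0.05/month) and uniform censoring over a window; the window
is chosen per experiment to reach the stated censoring fraction (70 months
≈ 30% at β = 0.7). All three generators are pure functions of their config:
one seed, byte-identical output.

What passing recovery tests do **not** show about real data: real cohorts
have correlated genes (co-expression modules), response-correlated library
composition shifts, patient dropout and non-exponential hazards, repertoire
sequencing depth effects and V-gene-dependent SHM hotspots — none of which
the generators model. The tests demonstrate correctness of the estimators
under the stated model, not robustness to these violations.

## Numerical and degenerate-input conventions

- TMM: samples with identical composition short-circuit to factor 1; an
  all-zero sample is an error, as is a single-sample matrix.
- BH: step-up with cap at 1, stable sort, input order restored.
- t-test: NaN p-values from zero-variance genes are set to 1, logged.
- KDE threshold: degenerate (zero-spread) distances fall back to 0.1.
- Cox: singular information matrices raise with a collinearity hint;
  non-convergence returns a flagged fit with the final score in the log.
- Pipeline: stages never mutate inputs; optional stages skip with a recorded
  reason; the manifest stores the config hash and per-stage outputs, and
  identical configs reproduce identical output bytes.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen to
make every estimator's behavior measurable in minutes on one CPU: 2000-gene
× 160-sample expression cohorts (20 replicates for the null control),
200-clone repertoires over 10 seeds, 100 threshold-detection draws, 2000
log-rank null simulations at 50 subjects/arm, 50-seed Cox recovery at
n = 300, and 50 + 200 interaction-model simulations at n = 200.
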