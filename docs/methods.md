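# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, the numerical conventions, and the design choices
made where the workflow is genuinely underdetermined.

## Filtering and normalization

Per-gene statistics are computed on the original log2 scale, before any
z-scoring (after z-scoring every gene mean is 0 and CV is undefined).
The mean uses all samples; the sd uses the n−1 (sample) denominator
throughout the package. "Scaled expression" is the min–max scaling of
per-gene means across genes to [0, 1] — a 0.12 floor is only meaningful
on a bounded scale, and this choice keeps the filter monotone in mean
intensity. CV = sd/mean is undefined for genes with mean ≤ 0; such genes
fail the CV criterion rather than raising an error. Both gates are
strict (`statistic > threshold`); a threshold of exactly 0 disables its
criterion, since under a strict gate a zero floor would still drop the
minimum-mean gene and constant genes, which is not what "no filtering"
means. Filtering precedes z-scoring; z-scoring a z-scored matrix is a
no-op up to floating error.

## Outlier removal

Case samples are embedded by classical (Torgerson) scaling: double-center
−½D², take the top-d eigenvectors scaled by √eigenvalue. The default
embedding uses Euclidean distances on the z-scored filtered matrix at
d = 2 (a planar embedding is what one inspects visually); at full
dimension the embedding reconstructs any Euclidean distance matrix to
machine precision, which the tests verify at 1e-6 relative error.
Eigenvalues within numerical noise of zero are treated as zero; genuinely
negative eigenvalues among the top d (non-Euclidean input) zero out their
axes with a warning.

The center for outlier distances is the **medoid** by default (centroid
by flag): the medoid is robust to the very outliers being hunted.
Distance z-scores use the sample sd; samples with z > 2 are flagged in a
single pass — no re-embedding iteration, because an iterated rule changes
the detection boundary in ways a reader of "mean + 2 sd" would not
expect. If all distances are equal the spread is degenerate: nothing is
flagged and the report says so.

## Clustering and cluster-count selection

Defaults are 1 − Pearson correlation between sample profiles and average
linkage — the customary choices for expression heatmap clustering; both
are configurable (Ward requires Euclidean input and is validated as
such). Cut labels are renumbered by first appearance so cluster 1 always
contains the first sample, making runs comparable.

Three internal validity indices score each candidate k (default 2–6):

- **connectivity** (L = 10 nearest neighbors, the conventional default):
  Σᵢ Σ_{j=1..L} 1/j over neighbor ranks j whose j-th neighbor is outside
  i's cluster; lower is better; distance ties break by sample order so
  the whole path is deterministic. Note that connectivity cannot
  distinguish any two k's whose clusterings both keep every
  L-neighborhood pure — it then ties toward the smaller k.
- **Dunn**: min between-cluster single-linkage distance over max
  within-cluster diameter; an all-singleton clustering has zero diameter
  and yields +inf.
- **silhouette**: mean of (b − a)/max(a, b); singleton samples
  contribute 0, the standard convention.

Each index votes for its best k; majority wins, ties toward the smallest
k, and the votes are recorded in the solution for inspection.

## Differential expression and the gene partition

"Student's t test" is read literally as the pooled-variance two-sample t
(Welch by flag). Degenerate rows are defined rather than left to NaN:
zero variance in both groups with equal means gives t = 0, p = 1; with
unequal means the groups are infinitely separated and the row gets p = 0
with an explicit degenerate flag. Significance is gated at BH q < 0.05
(raw-p gating by flag); q-values come from the step-up definition
q_(i) = min_{j≥i} m·p_(j)/j via statsmodels, and the tests pin them to a
brute-force implementation of the definition. The between-subtype
contrast and the two subtype-vs-control contrasts all run on the
z-scored filtered matrix (the same representation the clustering saw; t
statistics are invariant to per-gene affine scaling, so this choice only
affects the reported group means). The partition is plain set algebra
over the two control-contrast significant sets: core = A ∩ B,
unique = symmetric differences.

## Enrichment and networks

The hypergeometric universe defaults to the **filtered** gene list — the
genes that could have been called significant — which guards against
filter-induced inflation; the full gene list is available by flag. Set
members outside the universe are ignored. BH q-values are computed over
all tested sets for transparency, but reporting follows the classical
gates: ≥ 2 overlapping input genes and p < 0.01.

The pathway-overlap fraction is |shared| / min(|gᵢ|, |gⱼ|) over each
set's **input** genes by default (how pathway graphs are customarily
drawn from a query list; full memberships by flag), with edges at ≥ 0.30.
"High-confidence" interactions are those with confidence ≥ 0.9 when a
confidence column exists; tables without one are taken at face value.
Induced modules contain no intermediate connector nodes: a regulator or
drug is attached only if it directly touches an input gene, and a single
such edge suffices (star-shaped drug panels are the expected picture).

## The synthetic cohort model

`generate()` draws per-gene baselines uniform on [4, 12] log2 units with
i.i.d. Gaussian noise (sd 1.0) — the additive-on-log behavior of array
intensities. Defaults: 2000 genes, two subtypes of 14 case samples, 8
controls, 3 outliers (so the case cohort is 31 samples of which 28
survive outlier removal), 5%/3%/3% core/unique-A/unique-B genes, effect
2.0 sd, outlier shift 6.0 sd. Planted shifts have a random sign per gene
and are **mean-preserving**: each planted gene is re-centered to its
drawn baseline so the group contrast never drags the gene's overall mean
across the expression filter. Planted-DE baselines draw from the
narrower window (5.8, 7.0) chosen so that, with the between-group
variance the shifts add, both filter criteria hold with wide margins —
this is the structural guarantee that the default filter retains every
planted gene. Outliers are case samples carrying an additional +6 sd
shift on a random half of the genes, mimicking a technically aberrant
specimen rather than label noise. All draws come from a single
seeded PCG64 generator; output is bit-identical for a fixed config.

Companion generators build one gene set per planted class (80% class
members, 20% null fillers — never members of another class, so
cross-list enrichment is structurally silent) plus null-only decoys, and
an interaction table with within-class PPI edges (confidence uniform on
[0.5, 1]), one regulator (8 targets) and one drug (5 targets) per class
at confidence uniform on [0.9, 1] so induction at the default floor
recovers them.

What the generator does **not** emulate: probe-level artifacts, batch
effects, correlated gene modules, heavy-tailed noise, dropout, or
class-imbalanced cohorts. Passing tests therefore demonstrate that the
pipeline recovers exactly the structure its model assumes — clean
mean-shift subtypes in independent Gaussian noise — and say nothing
about robustness to those real-data complications.

## What recovery the conditions support

At the default conditions the discovery chain is essentially exact: in
20 seeded cohorts the 3 planted outliers are flagged exactly, k = 2 wins
with unanimous votes, and the k = 2 labels match the planted subtypes at
ARI 1.0, in 20/20 runs each. The gene-level results are *statistically*
as good as the test allows but not set-exact: with 14 vs 8 samples at
effect 2.0 sd, the per-gene noncentral t sits near 4.5, so each planted
gene is missed a few percent of the time, and BH at q < 0.05 spends
close to its 5% false-call budget among ~200 calls. Consequently the
recovered core/unique partition is a high-fidelity but not identical
image of the planted classes (core Jaccard ≈ 0.8; between-subtype recall
≈ 0.98 with aggregate false-call fraction ≈ 0.05). The test suite
asserts exactly these calibrated properties; set-exact recovery is not a
property this design can deliver and is asserted nowhere except as an
explicitly failing bound kept for transparency.

## Numerical conventions

Distance ties break by sample order; vote ties toward smaller k; all
stochastic behavior lives in the generator's seed, so the discovery path
is deterministic given input and config. Pipeline TSV/JSON outputs
serialize floats at 6 significant digits, making reruns byte-identical
across platforms; the run manifest records config, library versions, and
sha256 checksums of every output. Problem sizes in the tests and the
acceptance script (20 cohorts of 2000 × 39; brute-force oracles at
n ≤ 12; full hypergeometric enumeration at universe ≤ 12) were chosen to
make every oracle exactly enumerable while keeping the whole suite in
the tens of seconds.

## Known limitations

The filter's scaled-mean criterion depends on the cohort's min/max mean,
so adding genes can change other genes' pass status. Connectivity with
L larger than the smallest true cluster cannot vote against merging
clusters (see above). The pipeline assumes complete matrices — readers
reject missing values, and imputation is out of scope. Probe→gene
collapsing (highest-CV probe per symbol) is available but off by
default, and identifier mapping is the caller's responsibility.
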