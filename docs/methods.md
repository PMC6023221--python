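# Methods

This note records the models implemented by `cypome`, the conventions
that had to be fixed where the underlying procedures are conventionally
under-specified, and what the synthetic-data tests do and do not show.

## Feature tables

Coordinates are kept 1-based inclusive, as stored in GFF3; no half-open
conversion happens anywhere.  A `GenomeAnnotation` iterates features in
(scaffold, start, end, id) order; scaffolds missing from the supplied
scaffold order are appended lexicographically (unanchored scaffolds of a
draft assembly behave like one trailing "unknown" chromosome).
Overlapping and nested features are permitted.  Family membership is the
annotation category: `gene`, `partial`, `putative_pseudogene` and
`pseudogene` mark family members; `background` marks every other genome
gene.  Because no single GFF3 attribute conventionally encodes this
status, the package defines its own `category=` attribute
(`pseudogene?` accepted as an alias for `putative_pseudogene`) and
defaults to `background`, or to `gene` when a family attribute is
present without a category.

## Physical clusters

Two consecutive family annotations on one scaffold are linked when

* gap ≤ `max_gap_bp` (default 200,000), measured end-of-first to
  start-of-second and clamped at 0 for overlapping annotations, and
* at most `max_intervening` (default 8) background genes intervene.

A background gene intervenes when its start lies strictly inside the
open interval between the pair; genes overlapping a cluster boundary
therefore count at most once per gap.  This strict-interior rule is a
package convention — "separated by N genes" does not by itself say how
boundary-overlapping genes are counted.  The rule is evaluated only
between *consecutive* family annotations, never across an intermediate
family member, and clusters are maximal linked chains with at least
`min_cluster_size` (default 2) members.  Unsorted input raises rather
than being silently re-sorted, to keep the ordering contract explicit.

Detection and the resampling null share one array core (per-scaffold
sorted coordinates + binary search for intervening counts).  Its
equivalence with an independent brute-force oracle — evaluate the
predicate on every consecutive pair with explicit loops, then take
maximal chains — is asserted over 500 random instances in the test
suite, so the fast path is never its own referee.

## Resampling tests

**Clustering enrichment.**  Each of `n_iter` (default 10,000) iterations
draws the family's size in features uniformly without replacement from
the *whole* merged annotation, flags the draw as the family (features
keep their true coordinates; only the family identity is permuted) and
records the clustered fraction.  The p-value is the plug-in estimate
`#(null ≥ observed) / n_iter`; an optional `(count+1)/(n_iter+1)`
correction exists but is off by default, so a reported 0 means "no null
draw reached the observed value at this iteration count".  One seeded
`numpy` generator drives all iterations; there is no per-iteration
reseeding.

**Co-expression.**  The observed statistic is the fraction, over
expressed features lying in a physical cluster, that share their
expression-cluster label with at least one other expressed member of the
same physical cluster.  The null permutes the labels uniformly among
*all* expressed family features — clustered and isolated alike — which
preserves the marginal label frequencies while destroying any
association with physical position.  This permutation design is a
declared modeling choice: "bootstrap" names the empirical-p procedure,
not a specific published null.  The statistic is invariant under
bijective relabeling, and the test suite checks Monte-Carlo agreement
with exhaustive enumeration on instances small enough to enumerate.

Calibration: when the family is itself a uniform random subset, the
p-values over 200 replicate data sets are uniform (Kolmogorov–Smirnov
p > 0.01 at `n_iter` = 500); this is asserted in the acceptance tests at
a 2,000-feature, 100-member scale chosen so the null statistic has wide
support (heavily discrete statistics make plug-in p-values lumpy).

**χ² enrichment** is Pearson's statistic without continuity correction
on contingency tables of category × expressed (or × level) counts;
degenerate tables (one row/column, zero marginals) raise.

## Classification thresholds

Hit filtering presets (identity %, query coverage, minimum alignment
length): family similarity (40, 0.70, –), pseudogene validation
(50, 0.30, –), same-species TBLASTN parsing (70, –, 50 aa), outgroup
TBLASTN parsing (50, –, 50 aa).  Coverage is alignment length over query
length from a single best HSP per pair — imported tables must already be
collapsed; coverage above 1 (gapped alignments) is not clamped.

Naming: the best hit (score desc, then identity desc, then subject id —
the deterministic tie-break is a package convention) keeps the registry
name strictly above 95 % identity, assigns only the family at 40–95 %,
and is novel below 40 %.  Whether the original 95 % rule meant local or
full-length identity is not specified anywhere; both entry points exist
(`pairwise_identity` computes full-length global identity with BLOSUM62
and affine gaps −10/−0.5, matches over all alignment columns including
gap columns) and outputs record which was used.  Provisional names for
novel members (`next_member_name`) append the next free integer within a
subfamily; official nomenclature remains an external curation step.

## Expression

FPKM uses library sizes equal to the total fragments counted per
experiment (externally supplied totals are accepted, and the synthetic
generator supplies genome-wide totals).  "Expressed" means FPKM > 0 in
at least two experiments.  Level thresholds are the 0.33/0.66 quantiles
(linear interpolation between order statistics; the estimator is an
argument and is recorded in output metadata) of all non-zero
per-experiment FPKM values pooled across *all* annotations, applied to
the six category averages with right-closed intervals: 0 → none,
(0, q33] → low, (q33, q66] → average, > q66 → high.  Two conventions
fixed here: quantiles pool the full annotation set (not only expressed
sequences), and boundaries close on the right.  In the degenerate case
of a single pooled value both thresholds coincide and the value bins as
"low" — the average band (q33, q66] is then empty.  Exact level
assignments near thresholds depend on the quantile estimator; analyses
replicated with a different estimator may flip boundary cases.

The per-class summary (mean/median FPKM over expressed-annotation ×
experiment cells) pools putative pseudogenes with pseudogenes.

## Co-expression clustering

Distance is d = 1 − Pearson r between category-average profiles;
zero-variance profiles get r = 0 against everything (d = 1) rather than
being dropped, keeping the expressed set intact.  Agglomeration is
complete linkage (scipy), cut at height 1 − cut_r with cut_r = 0.656 by
default.  For complete linkage the cophenetic height of a cluster is its
maximum pairwise distance, so cutting at 1 − cut_r and cutting at the
correlation cut coincide, and every emitted cluster satisfies
min-within-pair r ≥ cut_r — asserted on every run in the tests.  Merge
ties are broken deterministically by scipy's lowest-index convention;
partitions near ties are therefore reproducible within this package but
not guaranteed to match other tools' tie-breaking.  Labels are letters
in dendrogram leaf order; reports also key clusters by dominant
category, since letter identities are an ordering artifact.  Heatmap
normalization is `(x − row min) / row max` — the denominator is the row
maximum, not the range.

## Synthetic data generator

`SimConfig` defaults emulate the motivating study system: a background
annotation of 29,971 genes on 19 scaffolds with exponential intergenic
spacing (mean 12 kb, gene lengths 1–6 kb), 48 family founders placed
uniformly, and Poisson(10) duplication events per founder.  Each event
copies a single member (or, with probability `p_segmental` = 0.2, a
block of 2–4 adjacent members) and places it tandem with probability
`p_tandem` = 0.6 — downstream of its parent at a gap ~ Uniform(1 kb,
`max_gap_bp`/2) with 0–3 intervening background genes — or uniformly at
random otherwise.  These rates were fixed once so that the emitted
families reproduce the descriptive shape of the study family (~600
sequences, ~80 % clustered, median cluster size 3, roughly half
complete genes with `p_pseudogenize` = 0.5).

Identity is additive decay on lineage paths: each event draws a decay
~ Uniform(2, 10) percentage points and a pair's identity is 100 minus
the summed decays along the tree path, floored at 20; cross-lineage
pairs draw Uniform(20, 35), below the 40 % family boundary.  Hits carry
coverage ~ Uniform(0.6, 1.0) and a score proportional to identity ×
alignment length.  This deliberately skips residue-level evolution —
sufficient to exercise every threshold — and `simulate_proteins` can
additionally mutate real residues along the lineage for alignment-level
tests.

Expression: each founder draws an archetype (one preferred category,
magnitude ~ LogNormal(μ = 1.5, σ = 1), baseline 0.3 FPKM elsewhere);
duplicates inherit the parent archetype with probability
`p_inherit_profile` = 0.75.  Non-gene copies are expressed at 10 % of
their archetype with probability 0.3 and silent otherwise.  Counts are
Poisson around FPKM × exon_kb × library_millions (libraries ~ 20 M ±
10 %) with multiplicative log-normal noise of CV 0.3; `noise_cv = 0`
returns the exact expected counts (the noise-free limit used by exact
tests).

What passing the synthetic tests shows — and does not.  The generator
produces the *structure* the analysis assumes: duplication-driven
clustering, lineage-correlated identity, archetype-driven co-expression.
It does not model assembly artifacts, allelic variants on unanchored
scaffolds, mappability or length biases in counting, overdispersion
beyond the log-normal–Poisson mixture, or correlated library effects.
Recovery results (cluster-detection ARI = 1 on tandem-only genomes,
monotone co-expression fraction in `p_inherit_profile`, calibrated
bootstrap p-values) therefore validate the implementations and their
null models, not the biological fidelity of any particular real-data
analysis.

## Problem sizes and numerics

The test suite runs at desk scale (hundreds to a few thousand features;
500 random oracle instances; 200 calibration replicates at
`n_iter` = 500; 5 × 100 replicates for the monotonicity check) and
completes in well under a minute; `scripts/acceptance.py` runs the full
study-scale conditions (~30,000 features, `n_iter` = 10,000) in a few
seconds, sizes chosen as the package's own verification budget.
Empirical p-values are exact counts over the null sample — no density
smoothing; quantiles and means use numpy/pandas defaults; all
randomness flows through `numpy.random.default_rng` seeded per call,
and identical seeds give byte-identical simulator output.
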