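# Methods

`metaprot` implements the quantitative analysis of a two-plex TMT 10-plex
fecal metaproteome study of diet-induced obesity: 4 high- and 4
low-responder mice sampled before (day 0) and after (day 56) an
obesogenic diet, 16 biological samples split 8 + 8 across two plexes,
with channels 126 and 131 of every plex carrying a pooled-standard
("bridge") aliquot.  This note records the models, the defaults and the
numerical choices; it states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## PSM filtering and aggregation

Quantitation starts from peptide-spectrum matches carrying per-channel
reporter signal-to-noise (S/N).  The QC filter retains exactly the PSMs
that are high-confidence, unambiguous, with isolation interference
≤ 25 % and mean reporter S/N ≥ 10.  Both thresholds are strict on the
removal side: interference exactly 25 and mean S/N exactly 10 are kept.
"Mean S/N" is the arithmetic mean over the PSM's 10 channels, the usual
Proteome Discoverer semantics.  Low-confidence PSMs are removed whenever
moderate-confidence ones are, since the moderate cutoff is the weaker
rule.

Protein quantities are sums of the surviving PSMs' reporter S/N per
channel.  A protein with no surviving PSM in a plex is explicitly absent
from that plex (NaN in its sample columns), never imputed; the analysis
set is then the intersection of proteins quantified in every plex.
Protein inference from shared peptides is out of scope: `protein_id` is
treated as already resolved.

## Bridge-channel normalization

For each plex with bridge columns *b* and sample column *s*:

    r_b(p, s) = value(p, s) / value(p, b)
    v(p, s)   = mean_b [ r_b(p, s) · median_p value(p, b) ]

i.e. each sample is expressed as a per-protein ratio to each pooled
standard, rescaled by that bridge column's median over proteins (which
restores a common S/N-like scale across plexes), and the two
bridge-derived values are averaged.  The arithmetic mean is the default;
a geometric mean (arguably more natural for ratios) is available.  Using
the mean of two independently noisy bridges halves the bridge-noise
variance contribution.

A final loading correction rescales so all sample medians agree:
with the default per-sample mode the matrix is divided column-wise by
its column medians and multiplied by the grand median *G* of that
column-normalized matrix, so every sample column ends with median *G*.
Computing *G* **after** the column division (rather than from *v*) is a
deliberate numerical choice: it makes the output exactly invariant to
rescaling any one plex by a constant — the property a batch correction
must have — while preserving the column-median guarantee.  A
global-scalar variant (divide the whole matrix by its grand median) is
available behind a flag for users who prefer untouched within-plex
column ratios.

Zero sample values pass through the ratio steps as zeros; a zero bridge
value for a retained protein is a hard error naming the protein, since
no ratio to the pooled standard exists.  On noise-free synthetic data
the normalized values equal each protein's true abundance divided by its
across-sample mean (true relative abundance), which the tests use as an
exact oracle.

## Differential abundance and the pi-score

Each contrast (final vs initial; high vs low responders at the initial
or final timepoint) is an unpaired two-tailed t-test per protein on the
normalized abundances — Student's equal-variance form by default,
matching common practice for small balanced designs; Welch is a flag.
The input is untransformed normalized abundance by default with a
`log2_input` option, since the scale the original analysis tested on is
not recoverable.

The ranking statistic is the pi-score

    π = log2(mean_A / mean_B) · (−log10 p)

with |π| > 1 as the significance cutoff (roughly α ≈ 0.05 for
fold-changes near 2).  Numerical policies: when one group mean is zero,
half the smallest positive matrix value is added to **both** means,
keeping the fold change finite and the statistic antisymmetric under
side-swapping; proteins with zero mean on both sides are excluded with a
notice; a zero-within-group-variance tie with unequal means gets a
p-value floored at the smallest positive double (with a warning) rather
than an undefined t.  No multiple-testing correction is applied in this
table — the cutoff is the raw π criterion; Bonferroni appears only in
term enrichment.

## Annotation composition and enrichment

Taxonomic composition of a protein set is the proportion per taxonomic
order (the rank at which the emulated study reports), with an
`unassigned` bin; proportions sum to 1.  Functional bias between an
enriched and a depleted set is the per-eggNOG-category log2 ratio of
within-set proportions; when either count is zero, 0.5 is added to both
counts of that category (continuity correction, preserving
antisymmetry).  Categories with ≤ 10 total proteins are flagged
unreported but kept in the table.  Headline fold differences are
computed on proportions, not raw counts, since the two sets differ in
size.

Term enrichment is the one-sided hypergeometric tail P(X ≥ k) for k of n
foreground proteins carrying a term against K of N background proteins,
with fold enrichment (k/n)/(K/N) and Bonferroni correction over the
tested terms.  The EASE variant (tail at k−1), the conservative score
DAVID reports, is off by default and available as a flag.  The tests
verify the p-values against exact combinatorial tail sums and check
calibration under uniform foreground draws.

## Multivariate structure

Bray-Curtis dissimilarities are computed between sample columns after
conversion to per-sample relative abundance (default; a raw-abundance
option exists), excluding bridge channels.  PCoA is classical metric
scaling: eigendecomposition of the double-centered squared-distance
matrix, coordinates scaled by √eigenvalue, axes ordered by decreasing
eigenvalue.  Negative eigenvalues are reported but their axes dropped,
with no Cailliez/Lingoes correction — transparency over adjustment.

PERMANOVA is the standard one-way decomposition of squared distances
into among- and within-group sums, with a label-permutation p-value
under the +1 convention (observed statistic included in the null), so
p ≥ 1/(permutations+1).  The statistic is cross-checked against
scikit-bio's implementation in the tests.  One caveat the tests encode:
with two groups of 4, a random shuffle recreates the separating
partition with probability 2/C(8,4) ≈ 0.029, so ~0.03 — not
1/(permutations+1) — is the attainable p-value floor for that design;
positive controls therefore use groups of 6 where the floor is ≈ 0.002.

Protein K-means uses Lloyd's algorithm on z-scored rows (so profile
shape, not abundance level, drives the grouping; min-max scaling is a
flag), k-means++ starts, best of 10 restarts by within-cluster sum of
squares, deterministic given a seed.  The within-cluster objective trace
of the winning run is retained and is non-increasing by construction —
an assertable invariant.  Per-cluster bias reuses the hypergeometric
machinery: each cluster's taxon/category composition against all
clustered proteins.  A 1 − Pearson leaf-ordering utility is provided
solely for heatmap export.

## Synthetic study generator

The generator emulates the *statistical* structure of the deposited PSM
tables, not spectra.  Per protein, a baseline abundance is log-normal
(meanlog 3.5, sdlog 1.0 on the S/N scale — a realistic 2–3 decade
dynamic range).  Planted effects multiply annotation-selected protein
subsets by 2^effect in the affected samples (final timepoint for the
diet contrast; high-responder samples of one timepoint for the responder
contrasts) and are recorded in a ground-truth ledger.  The default
effect structure mirrors the emulated study qualitatively:
Lactobacillales up and Clostridiales/Bacteroidales down after the diet,
plus responder-linked microbial and host effects.

Bridge channels carry the pooled mean of all 16 samples' true
abundances — the same pool in both plexes — times the plex's batch
factor, with independent noise per bridge aliquot (averaging two bridges
is only meaningful if they differ stochastically).  Reporter noise is
multiplicative log-normal per PSM per channel (σ = 0.25 natural-log,
~25 % CV, typical of MS3 reporter quantitation); S/N is positive and
heteroscedastic, so additive Gaussian noise would be wrong.  Default
batch factors are (1.0, 1.6).  PSM counts per protein per plex are
1 + Poisson(mean − 1) with mean 3 — the count model is a free choice,
undocumented in the emulated study.  Each PSM's channel values are
scaled by 1/count so the per-protein summed S/N equals true abundance ×
batch factor exactly at zero noise, giving downstream stages an exact
oracle.

Clean PSM rows whose channel mean falls below an S/N floor (12) are
rescaled up by a common row factor — this keeps them clear of the QC
filter without touching bridge ratios, since a whole-row scale cancels
in every ratio.  QC violators are planted explicitly (3 % moderate/low
confidence, 2 % ambiguous, 3 % interference above 25 %, 3 % sub-10 mean
S/N, relative to the clean count), each failing exactly one rule, with
deliberately distorted quantities so that a filtering failure would be
visible downstream; their identities are recorded for exactness tests.
Interference is uniform on (0, 25] for clean PSMs and uniform on
(25, 80] for the planted tail.

What the generator does **not** emulate: peptide-level sequence
structure, shared/razor peptides, missing channels, correlated noise
across PSMs of a protein, compositional closure of the microbiome, or
search-engine FDR behavior.  Passing recovery tests therefore shows the
pipeline's statistics behave correctly under the stated noise model, not
that real instrument data meet that model.

## Problem sizes and determinism

The test suite and acceptance script run the full design at 2,000
proteins (≈ 13,000 PSMs), with 500-replicate calibrations at 199
permutations and recovery checks across 5 seeds — sizes chosen so the
complete analysis of one study runs in about a second while keeping
Monte-Carlo error small.  All randomness flows through
`numpy.random.default_rng` seeds; the pipeline derives generator,
PERMANOVA and K-means seeds from one master seed via `SeedSequence`, and
a rerun with the same config reproduces every output byte-identically.

## Known limitations

- Single-factor PERMANOVA only; no multi-factor or stratified designs.
- No variance-moderated (empirical-Bayes) tests; with n = 4 per group
  the raw t-test is noisy for low-abundance proteins.
- Normalization offers no internal-reference-scaling or
  variance-stabilizing variants; zero bridge values are fatal rather
  than imputed.
- The annotation tables are taken as given; no taxonomic or functional
  assignment from sequence is performed.
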