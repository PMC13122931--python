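# Methods

## Region definition

The genome is partitioned into CpG-cluster regions: adjacent clusters less
than 400 bp apart (strict inequality, measured end-to-start) are merged,
and merged regions with fewer than 3 CpG sites are discarded. When no seed
intervals are supplied, seeds are the maximal runs of CpGs spaced < 400 bp;
this single-pass clustering already satisfies the merge post-conditions, so
re-segmenting a segmentation is the identity. Reads spanning two regions
are assigned to the region containing the majority of their CpGs, ties to
the leftmost; only in-region CpG calls contribute downstream. All
coordinates are 0-based half-open (BED convention) throughout.

## Fragment-level methylation entropy

Each qualified fragment contributes BiEn(s) = (1/(2^(n-1)−1)) Σ_k H(p(k))·2^k,
where p(k) is the fraction of ones in the k-th binary derivative (adjacent
XOR) of the fragment's methylation string and H is binary Shannon entropy
with the 0·log 0 := 0 convention. The 2^k weights emphasize the deepest
derivatives: periodic strings (1010…) have near-constant derivatives and
score low, irregular strings score high, constants score exactly 0, and
complementation leaves the score unchanged. Qualification: 3–32 CpG calls
after trimming missing calls at the read ends; a missing call strictly
inside the (trimmed) call string disqualifies the fragment. `bien` itself
accepts n = 2 for library use even though the region filter requires ≥ 3.
The per-region, per-sample value is the arithmetic mean over fragments and
the fragment count N is recorded as effective depth; N = 0 yields a missing
cell, never 0. A vectorized implementation (`bien_array`) grouped by
pattern length handles cohort-scale matrices; its agreement with the
scalar recurrence is unit-tested, and the scalar path is itself tested
against an independent direct evaluation on every binary string of length
≤ 10 at 1e-12.

## U-reads abundance (URA)

Reads with at least four observed CpG calls get u = C/(C+T) over observed
calls only (missing calls excluded from both counts). Classes: U if
u ≤ 1/4, M if u ≥ 3/4, X otherwise — both boundary inequalities inclusive.
URA = U/(U+X+M) per region and sample, reported only at ≥ 50 effective
reads, otherwise missing. The same epiread stream feeds the entropy and
URA computations, but the filters (3–32 CpGs vs ≥ 4 CpGs) are applied
independently.

## Fragmentation profiles

Autosomes are tiled with 100 kb bins (final partial bin kept at reduced
width; sex chromosomes excluded). Bins overlapping a blacklist are removed,
then the lowest-coverage 10% of the remainder (reference coverage is an
explicit input; ties break by genomic order, earlier bins dropped first).
Survivors aggregate into 1 Mb bins. Fragment length classes are
left-closed/right-open — short [100,150), middle [150,260), long [260,320]
with a closed upper end — so the three classes partition [100, 320];
lengths outside contribute nothing. Each classed fragment increments
exactly one 1 Mb bin, chosen by its midpoint, avoiding double counting at
bin edges. Per bin the three class coverages and their sum (nfrags) form
the 4-per-bin feature vector. PCA (after per-feature centering and unit
scaling fitted on training samples; zero-variance features dropped with a
warning) retains the smallest component count whose cumulative explained
variance reaches 98% — the "top 98% of principal components" is read as
cumulative variance, not 98% of the component count, matching the standard
DELFI-style workflow.

## Preprocessing and binary feature selection

Entropy and URA matrices (not fragmentation) are preprocessed by masking
cells with effective depth < 50 and dropping regions missing in > 90% of
samples; the drop decision uses training rows only so the test split cannot
influence the feature space. Per region, on training samples: delta = case
mean − control mean; the specificity cutoff is the ⌈0.8·n_controls⌉-th
order statistic of the controls in the favorable direction, with cases
strictly beyond it counted as sensitivity; the P-value is a two-sided
Wilcoxon rank-sum test (chosen as the distribution-free companion of the
Kruskal–Wallis/Dunn machinery used for tissue-of-origin selection; the
original description does not name the test). Thresholds are conjunctive:
|delta| ≥ 0.02, sensitivity ≥ 0.4 (entropy) or ≥ 0.5 (URA), P < 0.01.
Survivors are filtered by impurity-based random-forest importance
(> 0.006 entropy / > 0.0055 URA, fixed seed, 500 trees).

One caveat is documented and tested rather than hidden: choosing the
favorable direction by the sign of delta slightly inflates null
sensitivity above 1 − specificity (the direction is selected post hoc);
with a fixed direction the exchangeability identity E[sensitivity] =
1 − specificity holds exactly, and `region_stats` exposes a `direction`
argument for that purpose.

## Tissue-of-origin marker discovery

Entropy arm: per cancer type, a one-vs-rest binary screen at the same
specificity/threshold machinery; the union of per-type hits is refined by
Boruta against the multiclass labels. URA arm: Kruskal–Wallis across the
seven types with Benjamini–Hochberg FDR at q < 0.05, then Dunn's pairwise
rank z-tests (standard rank-sum z with tie correction, implemented here
because no installed package provides Dunn's test) attributing a region to
a type when that type separates from every other type, then per-type
Boruta ranking truncated to the top 30 by mean importance across
iterations (the ranking statistic is unstated in the original description;
mean importance over Boruta iterations is used).

Boruta implementation: each iteration appends a column-permuted shadow copy
of every feature, fits a random forest, and scores a hit for features
beating the best shadow importance; a two-sided binomial test across
iterations at α = 0.01 with Bonferroni correction confirms or rejects,
and features still undecided after max_iter (default 25; 100 trees per
iteration) are excluded as tentative. Type-I control (permuted labels
confirm nothing) and planted-feature recovery are tested by simulation.

## Models

Binary per-modality models: logistic regression for entropy and URA
features; elastic-net logistic regression (saga solver, l1_ratio 0.5,
C ∈ {0.1, 1} chosen by internal 3-fold CV) on the PCA scores for
fragmentation. NA cells are imputed with per-feature training medians and
features standardized with training statistics; both are baked into the
fitted bundle so prediction never refits. The decision threshold is
Youden's J on training scores (the original work reports an operating
point without stating its rule).

Fusion (EMCED): the mechanism is unstated in the source description;
this package stacks the per-modality scores with a logistic regression.
To avoid leakage the stacker is trained on out-of-fold sub-model scores
from an internal stratified 5-fold split of the training set; at predict
time the full-data sub-models score the new samples and the stacker
combines them. Stacking handles the heterogeneous dimensionalities
(a handful of regions vs PC blocks) and reproduces the expected monotone
E → E-M → E-M-F improvement structurally. Absent or constant modalities
degrade gracefully to fewer-modality fusion.

Tissue of origin: entropy uses one-vs-rest logistic regressions with the
sex covariate added to the ovarian sub-model only; URA and fragmentation
use multinomial elastic-net logistic regressions with sex as a global
feature. Per-modality 7-class probability vectors are fused by arithmetic
averaging and renormalization (parameter-free and order-independent);
ranking ties break by alphabetical type order. TOP1/TOP2 are read off the
fused ranking, so TOP2 ≥ TOP1 by construction.

Evaluation: AUC by the rank statistic with ties averaged (verified against
a brute-force pair-counting oracle), sensitivity/specificity with
Clopper–Pearson 95% intervals, stratified 5-fold cross-validation with
seed-reproducible folds.

## Interception (stage shift)

Cancers progress I → II → III → IV; a screening test has non-decreasing
cumulative sensitivity per stage and marginal sensitivity = difference of
consecutive cumulative values. The published recurrence

    detectable_s = original_s · marginal_s + slipped_{s−1}

does not state what happens to the original_s·(1 − marginal_s) remainder,
so two variants ship. The default `literal` variant applies the recurrence
as printed: a screened stage intercepts its detectable pool, an unscreened
stage lets it slip onward, and never-detectable individuals are diagnosed
at their original stage — so zero sensitivity reproduces the original
distribution exactly. The `conserving` variant screens everyone arriving
at a stage (original plus slipped) with the marginal sensitivity,
non-interceptees slip, and the stage-IV residue is diagnosed at IV; total
mass is conserved to machine precision. Both are deterministic and
monotone: raising any single marginal sensitivity (others held fixed)
never decreases total interceptions. The survival summary is the
count-weighted mean of per-stage 5-year survival over a final stage
distribution. Progression-speed scenarios are expressed as screening
schedules (`screened` flags per stage) since no progression rates are
published.

## Synthetic cohorts

The generator emulates targeted bisulfite sequencing of plasma cfDNA.
Regions are CpG runs (5–12 CpGs, 30 bp spacing) laid 2 kb apart on a toy
two-autosome genome (2 × 5 Mb). Read depth per sample and region is
Poisson around 80 (two designated regions at half depth so the depth < 50
and ≥ 50-read filters fire stochastically). Each read's methylation string
comes from a two-state Markov chain: initial methylated probability p0 and
switch probability s between adjacent CpGs. Low s yields ordered blocks
(low BiEn); raising s raises entropy without changing mean methylation —
disorder and methylation level are independent dials. 3% of reads get a
missing edge call (trimmed) and 2% an internal missing call (dropped),
exercising the filters.

Planted effects: in informative regions, an affected cancer sample's reads
are replaced, independently per read, by a hypomethylated tumor read
(p0 = 0.03, s = 0.02 → a U read) with probability load·0.35, or by a
disordered tumor read (p0 = 0.5, s = 0.05 + 0.30) with probability
load·0.35, where the tumor load is uniform on [0.5, 1] per cancer sample.
A per-(sample, region) shedding factor (uniform 0.6–1.4) decorrelates the
planted regions — without it every informative region is driven by the
single latent load and the markers are perfectly collinear, an unrealistic
degeneracy. Informative regions start mostly methylated (p0 ∈ [0.6, 0.9])
so the hypomethylation shift is one-signed. Binary-informative regions
affect all cancer samples; each cancer type additionally gets its own
disjoint informative regions. Fragment lengths follow a short/middle/long/
out-of-range mixture (0.15/0.70/0.10/0.05 for controls) with
load-scaled mass (default 0.08) moved from middle to short in cancer
samples; positions are uniform over the toy genome.

Presets mirror the modeled study's cohort shape: 197 cancer / 157
non-cancer training and 91 / 76 testing samples, with the seven cancer
types split proportionally (colorectal 46/21, esophageal 21/9, liver
21/10, lung 35/16, gastric 31/15, thyroid 18/8, ovarian 25/12); ovarian
samples are always female. `null` zeroes all effects; `strong-signal`
uses the defaults above, sized so planted regions clearly exceed the
selection thresholds; `seven-type` strengthens per-type effects (4 regions
per type, larger shifts) for tissue-of-origin work. The toy problem size
(50 regions, depth 80, 2000 fragments/sample) is the package's chosen
desk-scale default: large enough for every filter and statistical stage to
operate in its intended regime, small enough for multi-seed runs.

What passing on synthetic cohorts does and does not show: it validates the
pipeline's statistical machinery, leakage discipline and recovery of
planted structure; it does not certify clinical performance. The generator
omits bisulfite conversion error, strand effects, sequencing error, GC and
mappability structure, batch effects, and realistic inter-region
correlation, and its planted effect sizes are by construction favorable.

## Numerical and design notes

- Missingness is always explicit (NaN / `NA` token), never encoded as 0.
- All stochastic stages (forests, Boruta shadows, CV folds, generator)
  take explicit seeds and are reproducible bit-for-bit.
- The specificity cutoff uses a deterministic order-statistic convention;
  "strictly beyond" makes tie handling reproducible.
- Degenerate inputs error loudly: single-class labels, all-NA regions,
  empty stage distributions, identical PCA samples, unsorted CpG input.
- Model bundles serialize with an embedded package-version tag.

## Known limitations

- The fragmentation arm carries no per-type planted signal, so its
  tissue-of-origin sub-model contributes only dilution on synthetic data;
  probability averaging tolerates this by design.
- Boruta's binomial decision needs ≥ ~13 iterations for a verdict at
  α = 0.01 with correction; very small max_iter leaves everything
  tentative (excluded).
- The adaptive-direction null-sensitivity bias described above is inherent
  to the published cutoff convention, not an implementation artifact.
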