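# Methods

## Scope and units of analysis

The package analyzes one tissue core per patient (aggregation across
multiple cores, when present, is an unweighted mean of their profiles).
The unit of clustering is the patient × compartment profile: the mean
RMS-normalized spectrum over all pixels labeled tumor or stroma in that
patient's core. Compartments with fewer than `min_pixels` (default 10)
labeled pixels are dropped, which is why a cohort can yield fewer stroma
samples than patients.

## Annotation

Each pixel spectrum is divided by its root mean square
(√(mean(x²))), so every retained spectrum has RMS 1; all-zero pixels
cannot be normalized and are excluded. IF channels are co-registered to
the IMS grid by area-weighted block-mean pooling: destination cell j
covers the source interval [j·n/m, (j+1)·n/m) on each axis and source
pixels contribute proportionally to their overlap, which handles
non-integer resolution ratios exactly and preserves the image mean.
Positivity thresholds default to Otsu's method per channel per core and
can be overridden with constants; the labeling rule is panCK ≥ t →
tumor, else vimentin ≥ t → stroma, else unassigned, so every pixel gets
exactly one label and panCK positivity always wins.

Peak annotation assumes negative-ion mode: an observed m/z is matched to
[M−H]⁻ = M − 1.007276 Da of each reference metabolite, keeping all
candidates with |ppm error| ≤ `tol_ppm` (default 5), sorted by absolute
error. The adduct list is configurable; only [M−H]⁻ is built in.

## Consensus clustering

Per iteration, ⌊0.8·n⌋ samples are drawn without replacement and
clustered by average-linkage agglomeration on the correlation distance
d(i,j) = 1 − Pearson(i,j) across metabolites; the single linkage tree is
cut at every K in 2..10. Consensus matrices share the pair-sampling
denominator: M_K(i,j) = co-clustered / co-sampled, with never-co-sampled
pairs set to 0 (with a warning; vanishingly rare at 1000 × 80%) and a
forced unit diagonal. A constant (zero-variance) sample has undefined
correlation; its distance to every other sample is defined as 1.

The empirical CDF of the upper-triangle consensus values is summarized
by its left-Riemann-sum area A(K) over [0, 1]. The delta-area rule sets
Δ(2) = A(2) and Δ(K) = (A(K) − A(K−1))/A(K−1) for K ≥ 3, and selects the
largest K with Δ(K) ≥ τ. τ defaults to 0.1: the original choice of K was
made by visual inspection of the delta-area elbow, and an explicit
threshold is required for automation; 0.1 separates the collapse of the
relative gain (typically below 0.05 past the true K on the synthetic
cohorts) from the large gains before it. If no K qualifies the rule
falls back to K = 2 with a warning, and a manual override
(`ConsensusResult.relabel(k)`) is provided.

Final labels come from average-linkage clustering of 1 − M_{K*} cut at
K\*, renumbered by descending cluster size (ties by smallest member
index), yielding the T1..Tk / S1..Sk convention. Subtype percentage
summaries use largest-remainder rounding so the printed percentages
always total 100. Separation is reported as the mean silhouette on the
1 − Pearson distance (samples in singleton clusters score 0); this
replaces ordination-based displays with a single scalar.

scipy's linkage implementation is deterministic for a fixed input
order, which provides the tie-breaking determinism the pipeline needs;
`cut_tree` guarantees exactly K clusters per cut.

## Statistics

Subtype–marker association uses one-vs-rest indicator coding (member = 1)
against each marker score, Spearman rho with mid-rank ties and a
two-sided t-approximation p, BH-adjusted over the full subtype × marker
family of a compartment; both raw and adjusted p are reported because
published correlation tables do not always state which was shown.
Group differences use the tie-corrected Kruskal–Wallis H with chi-square
p and post hoc Dunn z tests on pooled mid-ranks (variance
(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ)), BH over pairs.
Clinicopathological columns are tested by chi-square unless any expected
cell is below 5, in which case a Fisher exact test is used — scipy's for
2×2 tables, a direct Freeman–Halton enumeration over all tables with the
observed margins for larger ones (capped at 2×10⁵ candidate tables, with
a chi-square fallback and warning beyond the cap).

Survival uses the product-limit estimator, the standard O−E log-rank
statistic (overall df = groups − 1, plus pairwise mode with raw p and an
optional BH column, matching the pairwise style of published subtype
comparisons), and Cox proportional-hazards fits with Efron tie handling.
Reference levels are the largest subtype and UICC stage I. Rank-deficient
designs are rejected before fitting. Both one-model (all subtype
indicators) and per-subtype fits are possible by constructing the design
accordingly.

Correlation networks test all metabolite pairs within one subtype's
samples (minimum 5) by Spearman correlation; the default filter is
BH-adjusted p < 0.001 — the stricter of the two published descriptions of
the cut — with a raw-p mode available. Isolated metabolites are dropped.
Enrichment is over-representation: hits = |network ∩ pathway|, expected
= pathway size × |network| / |background|, ratio = hits/expected, p =
hypergeometric upper tail, BH across pathways; the background is the
full annotated metabolite set of the cohort. A quantitative
(globaltest-style) variant was considered and not implemented because
only enrichment ratios and metabolite counts are needed downstream; this
is recorded as an interpretation, not a claim of equivalence to any
specific online tool.

## Classifier transfer

The published transfer used an externally trained machine-learning
classifier whose specification (and 100-metabolite panel) is not public;
the package substitutes a transparent nearest-centroid model, clearly
its own design: features are z-scored on the training cohort, the panel
is the top `panel_size` (default 100) metabolites by Kruskal–Wallis H
across subtypes, and centroids are per-subtype medians in z-space
(robust to the log-normal skew of intensities). Assignment is nearest
centroid by Euclidean distance, ties to the lower subtype index; new
samples are always standardized with the stored training means/SDs
(never re-standardized on the new cohort), with missing panel features
imputed at the training median and a hard error below 80% panel
coverage.

## Synthetic-data generator

The generator emulates the study conditions, not the instrument: one
core per patient on a 16×16 grid, log-normal intensities (baseline
log-intensity per metabolite ~ N(3, 1), exponentiated), four planted
subtypes per compartment with a configurable standardized shift
(`effect_size`, default 3) on that subtype's block of informative
metabolites (default 30% informative, split evenly into per-subtype
blocks), patient-level biological noise (sd 0.5 on the log scale) and
pixel-level noise (sd 1). The first `tumor_fraction` (default 0.6) rows
of pixels are tumor; IF channels are produced at 2× grid resolution with
the positive channel bright (≈1) and the negative dim (≈0.05) plus
Gaussian noise, so Otsu thresholding recovers the planted mask. Stroma
subtypes mirror tumor subtypes with probability `subtype_coupling`
(default 0.7), planting the tumor↔stroma co-membership structure.

Marker scores arise from a Gaussian latent shifted per planted subtype
(default: subtype 1 immune-cold with negative CD3/CD8/PD-L1/γH2AX
shifts, subtype 2 immune-hot, subtype 3 neutral, subtype 4 PD-L1⁺ with
elevated DNA damage) pushed through monotone maps into native ranges
(logistic × 100 for PD-L1 %, logistic for the γH2AX proportion,
exponential for CD3/CD8 scores) — monotone transforms preserve the
planted Spearman signs. Survival is exponential with per-subtype
multiplicative hazards (default 1.0, 0.8, 0.45, 1.2; base median 30
months — subtype 3 protective) and independent U(0, τ) censoring with τ
calibrated by root-finding so the expected censoring fraction equals
`censor_rate` (default 0.3). Clinical staging columns are drawn
independently of subtype with marginals shaped like a resected cohort,
so clinicopathological tests are null by construction.

The NAC-style transfer cohort (default 40 patients) draws z-space
profiles around the fitted classifier's centroids with `noise_sd`, and
assigns the response label directly: resistant with probability 0.9 in
the designated resistant subtype versus 0.3 elsewhere, with survival
drawn conditional on the label (hazard ×3 for resistant patients), so
the short/long-term-survivor split at the median is consistent with the
label while the planted enrichment stays an exact ground truth.

What the generator does **not** emulate: FT-ICR peak shapes, isotope
patterns, mass-error structure, spatial autocorrelation within a core,
multiple cores per patient, batch effects and missing pixels. Passing
tests therefore demonstrate correctness of the computations under a
clean planted-signal model, not robustness to those real-data artifacts.

All randomness flows from one integer seed through named SHA-256-derived
SeedSequence substreams (one per stage), so any stage rerun in isolation
reproduces its draws and fixed-seed runs are byte-identical.

## Problem sizes and numerical choices

The recovery and K-selection experiments use 300 patients, 100
metabolites and 500 resampling iterations over K = 2..10 with five
seeds; the test suite's unit-level checks use 8–200 samples, which is
where the brute-force oracles (exhaustive partitions, pair-by-pair
consensus recounts, direct partial-likelihood maximization, exact
hypergeometric enumeration) remain feasible. One iteration computes one
linkage tree and cuts it at every K, which is algebraically identical to
per-K clustering of the same subsample because the tree does not depend
on K. Tiny negative correlation-distance values from floating-point
rounding are clipped to 0; consensus matrices force an exact unit
diagonal.

## Known limitations

Exact discrete tests (Fisher) have conservative, super-uniform null
p-values — calibration checks assert P(p ≤ α) ≤ α rather than exact
uniformity. The delta-area rule with τ = 0.1 is a heuristic replacement
for visual elbow selection and can fall back to K = 2 on structureless
data. The centroid classifier is a stand-in for the original published
classifier, not a reimplementation of it. Pathway enrichment is
over-representation only (no topology or quantitative scores), and the
bundled pathway catalog builder produces synthetic block catalogs for
testing rather than curated biology.
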