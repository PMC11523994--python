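# Methods

## Copy-number model and purity correction

Profiles live on a fixed grid of 100-kbp bins (the working resolution of
shallow-WGS read-depth profiling). Each tumor carries observed and segmented
log2 ratios, a 5-level call per bin (−2 homozygous deletion, −1 loss, 0
neutral, +1 gain, +2 amplification) and a purity estimate p ∈ (0, 1].

An observed ratio mixes tumor and diploid normal signal,
2^r = p·2^(r_t) + (1 − p). The correction inverts this map:
r_t = log2(max(ε, (2^r − (1 − p))/p)), ε = 2⁻¹⁰. The floor keeps the
logarithm finite when a deep deletion at low purity pushes the observed
ratio below the contamination baseline; ε corresponds to a residual copy
number of ~0.002, far below any biologically meaningful dosage. The
inversion is exact above the floor (round-trip tested to 1e−9). Published
cohorts do not print the correction formula their purity tool applies
internally; this admixture inversion is the generative model those tools
assume and is our explicit choice. Whether upstream peak-level values are
segment means or marker means is likewise not observable downstream; we use
segment means.

Segments are rasterized onto the grid by midpoint membership (a bin belongs
to the segment containing its midpoint); bins covered by no segment are
masked per sample. Coordinates are 1-based inclusive internally (SEG
convention); BED input is converted on read.

## Peak summarization and nearest-centroid assignment

The classification space is a catalog of recurrently gained/deleted regions
(GISTIC-style peaks) with a direction and a source cluster each;
sex-chromosome peaks are removed before classification because male/female
dosage shifts the log2 baseline. The value of tumor s at peak j is the
length-weighted mean of the purity-corrected **segmented** log2 over usable
bins overlapping the peak (segmented rather than observed values: robust to
bin noise, and reference cohorts cluster on segmented data). Peaks
overlapping no usable bin are missing for that sample.

Centroids are per-peak arithmetic means over a labeled reference cohort,
computed per cluster (a pooled grand mean would give one centroid and no
classification rule); peaks missing in >50% of either cluster's samples are
dropped as unstable. Assignment minimizes Euclidean distance computed over
the sample's non-missing dimensions, with the SAME dimension subset for both
centroids — missing dimensions are dropped from both, not imputed, so the
two distances stay comparable. Exact ties (measure-zero in practice) go to
GS with a flag, making assignment deterministic. The reference labels are an
input; the package does not re-derive the original reference clustering.

## Genome instability index

GII = 100 × altered-bp / called-bp over usable bins; with equal-width bins
this is a bin-count fraction. Unusable bins leave both numerator and
denominator. The GII-low/high threshold is the maximally selected log-rank
cutpoint: candidates are the unique observed values whose split leaves at
least minprop = 0.1 of samples on each side (the convention of the
surv_cutpoint tool family; rank-based, hence invariant to monotone
transforms); g\* maximizes |standardized two-group log-rank z|, ties toward
the smaller cutoff. No p-value is attached to g\* — the maximally selected
statistic's null distribution is not chi-square(1), and the package only
uses the location of the optimum.

## Survival statistics

*Kaplan–Meier.* Product-limit estimate with Greenwood variance; 95% CIs on
the log-survival scale (S·exp(±1.96·se(log S))), the survival-ecosystem
default. Curves record a truncation time — the first time fewer than 10% of
the group remains at risk — as a reporting limit only; no data are deleted.

*Log-rank.* The k-group unweighted test is delegated to lifelines; a fast
numpy implementation of the two-group standardized statistic
(O₁ − E₁)/√V backs the cutpoint scan and the survival tree and is tested
against lifelines and against exhaustive permutation at small n.

*Cox.* Partial-likelihood maximization with Efron tie handling via
lifelines; categorical terms are treatment-coded against an explicit
reference level. Wald CIs/p per coefficient. Backward selection drops whole
factors (all dummy columns together) by likelihood-ratio p — refit without
the factor, 2Δℓ against chi-square with the factor's df — removing the
largest p ≥ 0.10 per round. The 0.10 threshold is the screening convention
for prognostic-model reduction.

*Survival tree.* Greedy recursive partitioning over categorical factors: at
each node every binary partition of every factor's observed levels is scored
by the two-group log-rank chi-square; the best split is kept if its nominal
chi-square(1) p < 0.05; recursion stops at depth 2 or below 20 samples per
node. This is a deliberate simplification of survival CART (no
exponential-model scaling, no pruning/cross-validation, no multiple-testing
adjustment of the split p); it is used to order split variables, not to
estimate honest split significance.

*Fisher r×c.* Two-sided by the probability criterion: p is the total
multivariate-hypergeometric probability of margin-matched tables whose
probability is ≤ the observed table's (ties included within 64·eps relative
tolerance, matching the reference implementations). Exact mode enumerates
all tables (vectorized over the first row for 2×c; depth-first otherwise)
and refuses above a configurable budget, directing the caller to Monte
Carlo: n_mc tables sampled from the margin-conditioned null by Patefield's
algorithm, p = (1 + #{prob ≤ observed})/(n_mc + 1). On a 3×3 fixture the
exact enumeration agrees with an independent reference implementation to
eleven digits. One-way ANOVA covers continuous covariates (age-style).

## Region comparison

Adjacent usable bins merge left-to-right into a region while the fraction of
samples whose call differs from the region's opening signature stays ≤ tau
(default 0.01); chromosome boundaries always split. This replaces the
information-loss criterion of the classical region-collapsing tool with a
directly testable rule of the same intent. For testing, calls collapse to
sign (loss/neutral/gain): the published comparisons report gains and losses,
not amplification strata. Per region a 2×3 chi-square is computed, its null
by relabeling samples B = 10,000 times (seeded stream, vectorized as three
matrix products), p = (1 + #{perm ≥ obs})/(B + 1). The FDR at each region's
observed statistic t is (mean permutation count of stats ≥ t)/(observed
count ≥ t), clipped to [0, 1] and made monotone q-value-style (tightening
the threshold never raises the estimate). Permutation p-values of a discrete
statistic carry point masses (notably at p = 1); the null-calibration test
therefore asserts one-sided agreement with the uniform (no
anti-conservativeness) plus a near-nominal rejection fraction, rather than a
two-sided KS against a continuous uniform.

## Synthetic cohorts

The generator emulates what the pipeline consumes, not raw reads: per
sample, a purity draw (Uniform(0.3, 0.9), the FFPE resection range), binary
event draws per template peak, integer copy states (baseline 2), observed
log2 = log2((p·c + 2(1 − p))/2) + N(0, σ²) with σ = 0.15 per bin, segmented
log2 = the noiseless mixture value, and calls derived from the true copy
state. Survival is exponential per stratum with λ = −ln(S₅)/60 per month,
calibrated to five-year rates (GS-intestinal 0.614, GS-diffuse 0.565,
CIN-intestinal 0.476, CIN-diffuse 0.315) under independent Uniform(0, 120)
censoring — a single-parameter law pinned to the printed five-year points;
default stratum sizes 24/57/142/86. Categorical covariates draw from
stratum-specific frequency tables (sex defaults to the published per-stratum
proportions).

The default grid is miniature — 3 chromosomes × 100 bins — carrying 24
one-Mb template events (CIN: gains at copy 3–4 with f 0.70–0.85 and
deletions at copy 1 with f 0.60–0.75; GS: chr8-style gains at f 0.30,
5% background elsewhere). The event frequencies were set by a power
calculation so that the cluster separation sits in the well-separated
regime the classifier targets (expected nearest-centroid misassignment
≲0.1% under the binary-event geometry); a genome-scale preset (22 autosomes
+ X, ~31k bins) serves catalog-bookkeeping and scale tests. The reference
panel draws peak-level vectors as template mean + N(0, σ_ref = 0.1), 150
samples per cluster.

What the generator does **not** emulate: wavy GC/mappability artifacts,
segmentation errors, purity-estimation error (the recorded purity is the
true mixing weight), subclonality, copy-neutral LOH, and correlated events.
Passing tests therefore demonstrate correctness of the statistical machinery
under the assumed generative model, not robustness to upstream profiling
artifacts.

## Problem sizes and numerical choices

Test simulations are scaled to the cohort sizes that make their targets
identifiable: n = 309 (default cohort composition) for classification and
composition checks, n = 1000 for cutpoint recovery, n = 2000 for hazard
ratios and the survival tree, n = 20000 for Kaplan–Meier vs the closed-form
exponential, 10⁶ draws for Monte-Carlo Fisher. Permutation defaults are
B = 10,000 in the API and a few hundred in tests. All randomness flows
through seeded `numpy.random.Generator` streams; same seed, same cohort,
bit-for-bit. Degenerate inputs: empty clusters, zero usable bins/dimensions,
constant markers, zero-margin tables and zero-event cohorts either raise a
typed error or return the defined degenerate value (Fisher p = 1 for a
single-row/column table), as documented per function.

## Known limitations

- The survival tree is a simplified partitioner; its split p-values are
  nominal and its topology should be read qualitatively.
- The permutation FDR estimator is a plug-in; with few regions it is
  coarse and conservative.
- Backward selection inherits the usual instabilities of stepwise
  procedures near the threshold.
- Exact Fisher enumeration is practical only for 2×c (or small r×c)
  tables; larger tables go through Monte Carlo, whose resolution is
  1/(n_mc + 1).
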