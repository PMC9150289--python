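# Methods

`concurgene` implements an integrated copy-number / expression analysis for
paired tumour cohorts: marker-level SNP-array log ratios are segmented and
called; genes whose dosage and transcription change coherently ("concurrent"
genes) are scored by rank correlation and combined across cohorts on the
Fisher z scale; and the resulting gene universe feeds two prognostic
models — a supervised principal-component survival model and a panel of
six cross-validated classifiers for dichotomous outcomes.  Every stage is
exercised on synthetic cohorts with known ground truth; this note records
the models, the defaults and the design choices.

## Copy-number segmentation and calling

**Circular binary segmentation (CBS).**  Each chromosome of each sample is
treated as a circle; the candidate change points are the arc `(i, j]` that
maximises the pooled-variance two-sample |t| between the arc and its
complement, and the split is accepted when its within-segment permutation
p value (label shuffling of the segment's markers, 1000 draws by default)
is at or below alpha = 0.01.  Recursion continues on each side until no
accepted split remains.  Degenerate pooled variances are resolved by
sending distinguishable constant arcs to t = infinity, which is what makes
noiseless piecewise-constant profiles resolve exactly.  On chromosomes
longer than 300 markers the arc scan evaluates a coarse endpoint grid
(about 256 points) and then refines exactly around the best pair; this
caps the quadratic cost and, on the profile scales used here, recovers the
same breakpoints as the exact scan.  Permutation testing stops early once
the add-one p value is guaranteed to exceed alpha.

**Smoothing and MergeLevels.**  Before segmentation (optional, on by
default) singleton outliers — points more than 4 robust SDs from both
neighbours in the same direction — are shrunk to the nearer neighbour
plus 2 SDs.  After segmentation, segment levels whose member-marker
distributions are indistinguishable genome-wide (Wilcoxon rank-sum
p > 0.05) are merged iteratively, most-similar pair first, recomputing
each level's mean over all member markers.

**Calling.**  Per-array noise is the unscaled median absolute deviation
(MAD) of that array's log ratios (a flag applies the 1.4826 consistency
factor).  Segments are called AMP above 1 x MAD, HOMDEL below -1 x MAD,
GAIN/LOSS beyond +/-0.5 x MAD, otherwise NEUTRAL; comparisons are strict,
so a mean exactly at a threshold takes the milder state.

**Recurrence (G scores).**  A marker's G score sums, over samples, the
aberration amplitude above theta = +/-0.1 of the segmented values.  The
null permutes each sample's marker values across the genome; because
markers are exchangeable under this null, the per-marker p value is read
off the pooled null distribution (all markers x all resamples), which
keeps the marker-level p values uniform on signal-free data.
Benjamini-Hochberg q values are computed across markers and significant
regions are maximal runs with q < 0.25.  Gene-set enrichment inside
regions uses equal-size random sets from the coordinate universe with the
add-one empirical p.

## Concurrent genes and meta-combination

Gene-centric copy number is the mean log ratio of the markers inside the
gene's interval (1-based inclusive; genes covering no marker are missing,
never zero).  Expression platforms with redundant probes are reduced to
one probe per gene by the largest interquartile range (ties: smallest
probe id), then median-centred per gene within each dataset.  Concurrency
is the midrank Spearman correlation of gene-centric copy number and
expression across shared samples, with the two-sided t approximation
(n - 2 df); genes with fewer than four complete pairs or constant input
are flagged undefined.

Correlations r1 (n1 samples) and r2 (n2) from two discovery cohorts are
combined as

    z_bar = ((n1 - 3) z1 + (n2 - 3) z2) / (n1 + n2 - 6),   z = arctanh(r),
    r_bar = tanh(z_bar),   V(z_bar) = 1 / (n1 + n2 - 6),

with a two-sided normal p on z_bar / sqrt(V).  The n - 3 weights are the
inverse Fisher-z variances, which is what makes the combination robust to
severely unequal cohort sizes (31 vs 345 in the default study design).
The universal concurrent set is the genes whose combined p clears
alpha = 0.001; 0.05 and 0.01 are the per-cohort screening conventions.

## Survival risk model

Genes are screened one at a time by the Cox proportional-hazards **score
test** at beta = 0 with Efron tie handling (validated against R
`survival::coxph`'s `sctest` to 1e-8); the score test needs no iteration,
which keeps nested cross-validation affordable.  Genes with p < 0.001 are
standardized (mean 0, SD 1) and the first principal component of the
selected submatrix (by SVD) supplies unit-norm loadings — the
"supergene".  A sample's prognostic index is the loading-weighted sum of
its standardized expression; because a principal component's sign is
arbitrary, the loadings are flipped if the training index's Cox score runs
opposite to hazard.  Risk groups cut the index at a percentile of the
training indices (50 by default, 75 for sensitivity analyses); "high" is
strictly above the threshold, ties go to low.

Evaluation is by nested leave-one-out cross-validation: screening,
loadings, orientation and the percentile threshold are all refit on each
fold's n - 1 samples, and per-fold thresholds are used rather than a
full-data cut, so the held-out outcome can never influence its own label
(an explicit leakage test flips held-out outcomes and asserts label
invariance).  A fold that selects no genes falls back to an unweighted
standardized-mean index cut at the fold's own percentile.  Risk groups are
compared by the two-group log-rank test, and discrimination by the
cumulative-case / dynamic-control AUC at a landmark time with inverse
Kaplan-Meier censoring weights (left limits at case event times; checked
against scikit-survival's IPCW estimator and, without censoring, equal to
the Mann-Whitney statistic).  The landmark defaults to the median
follow-up of the censored samples and is otherwise a user input.

*Known limitation.*  The log-rank p value on cross-validation-derived risk
groups is mildly anti-conservative whenever univariate screening succeeds
spuriously, and the effect grows with the number of screened genes (with
49-gene panels, the size this model consumes, measured null rejection is
4-7% at nominal 5%; with several hundred genes it can exceed 15%).  A
permutation-calibrated log-rank reference would remove this and is left to
future work.

## Class prediction

Dichotomous outcomes use the pooled-variance two-sample t filter at
alpha = 0.001, a global multivariate permutation test on the count of
filter-passing genes, and six classifiers: compound covariate predictor
(t-weighted expression sum, cut at the midpoint of class mean scores),
diagonal linear discriminant analysis (shared per-gene pooled variance),
1- and 3-nearest neighbours and nearest centroid (Euclidean distance on
training-standardized genes), a linear soft-margin SVM at cost 1, and the
Bayesian compound covariate (Gaussian class-conditional densities of the
compound score, pooled variance, equal priors, class-1 posterior
reported).  All supervised steps are refit inside every leave-one-out
fold; a fold whose filter passes nothing falls back to its single
smallest-p gene.  Permutation p values rerun the entire cross-validation
per label shuffle with the add-one correction; the CV-AUC of the Bayesian
variant is the Mann-Whitney area of cross-validated posteriors against
the true labels (ties count half).

## Synthetic cohorts

The generator emulates the paired design the pipeline targets, and its
defaults are the study conditions used by the tests:

| parameter | default | meaning |
| --- | --- | --- |
| genome | 3 chromosomes x 1000 markers, 1 kb spacing | desk-scale genome; 600 genes covering 2 markers each |
| `seg_event_rate` | 4.5 events/sample/chromosome | with geometric segment lengths (mean 110 markers) about half the genome is aberrant, a chromosomal-instability-like load |
| magnitudes | gain/loss +/-0.3, amp/del +/-1.0 | log-ratio shifts; later events overwrite earlier ones |
| `marker_noise_sd` | 0.15 | per-marker Gaussian array noise |
| `concurrent_fraction` | 1/6 | 100 of 600 genes carry a dosage effect |
| `dosage_beta` / `expr_noise_sd` | 2.5 / 0.35 | sized so dosage-driven genes show true Spearman rho ~ 0.6 in both discovery cohorts |
| `signature_factor_sd` | 0 (0.35 in survival scenarios) | shared latent factor across signature genes; models the co-expression of a prognostic programme, without which no first-PC summary could recover the risk direction |
| `log_hazard_coef` | 1.0 (2.0 in planted-signal scenarios) | exponential event times with log hazard proportional to the standardized mean signature expression |
| `censoring_rate` | 0.7 | independent Uniform(0, c) censoring with c solved numerically; matches the heavy censoring typical of the registry cohorts this design emulates |

All randomness flows from one integer seed through named substreams, so
identical seeds give bit-identical cohorts even when stages re-run in
isolation.  Multi-cohort simulation shares the genome, the concurrent set
(with slopes) and the signature across cohorts while drawing independent
noise, emulating unequal discovery cohorts (31 and 345 samples by
default) and redundant-probe validation platforms.

What the generator does **not** emulate: GC waves and batch effects,
B-allele frequencies, tumour purity/ploidy, probe-specific biases beyond
iid noise, non-linear dosage response, and gene-gene co-expression beyond
the CNV-induced and signature-factor structure.  Passing tests therefore
demonstrate parameter recovery under the stated noise model, not
performance on real arrays.

## Numerical choices and degenerate inputs

- Permutation p values use the add-one correction throughout, so they are
  never zero and never below 1/(1 + draws).
- CBS comparisons accept a split at p <= alpha; boundary ties in the arc
  scan resolve to the first maximum in row-major order, deterministically.
- Undefined statistics (constant covariates, < 4 complete pairs, zero
  pooled variance with equal means) are flagged NaN and excluded by
  filters rather than silently passed.
- Missing model genes at prediction are imputed at the training mean
  (zero after standardization); more than half missing is refused.
- MAD = 0 arrays trigger a warning: every nonzero segment becomes a
  high-level call.
- File dialects are tab-delimited with headers, `repr`-precision floats
  and verbatim chromosome labels; write-read round trips are exact, which
  is what makes seeded pipeline reruns byte-identical.

## Scale of the shipped experiments

Test and acceptance scenarios are sized for a single CPU: 100-replicate
CBS recovery at 100 markers, 31/345-sample discovery cohorts with 600
genes, 50-sample recurrence scans at 1000 resamples, one 200-sample
planted-signature cohort plus 100 null cohorts of 60 samples for the
survival model, and 20+20-sample classification with 199-permutation
p values.  These sizes reproduce the qualitative behaviour of the
method's published use at a fraction of the cost; all counts are
configurable.
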