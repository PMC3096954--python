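# Methods

This package re-implements the computational machinery used to define and
characterize the claudin-low intrinsic subtype of breast cancer: expression
preprocessing, SAM-based gene selection, Euclidean centroid subtype
predictors, a DWD-based mammary differentiation score, gene-signature
analysis, and the association/survival statistics — exercised end to end on
a synthetic cohort generator.  This note documents the models, the
parameters that matter, and the design choices made where conventions
genuinely diverge.

## Expression preprocessing

Input is a probe table of normalized log2 (sample/control) ratios with raw
channel intensities.  A probe is retained iff its lowest sample intensity
*and* its lowest control intensity across arrays exceed the threshold
(default 10, the customary two-colour floor).  The filter is applied over
all arrays jointly rather than per array; this is the stricter reading and
is flagged as a sensitivity point, since per-array filtering would retain
more probes.  Surviving probes of the same gene are collapsed by unweighted
arithmetic mean (missing values ignored), genes are median-centered within a
data set, and samples are standardized to zero mean, unit variance
(population variance), in that order.  Genes whose rows are entirely missing
are dropped; a zero-variance sample under standardization is an error naming
the sample, never a silent NaN column.

## SAM gene selection

Per gene, d = (mean₁ − mean₂)/(s + s₀), with s the pooled-variance standard
error of the mean difference (paired design: the standard error of the
within-pair mean difference) and s₀ the fudge factor chosen as the
percentile of {s} minimising the coefficient of variation of the spread of d
across bins of s (median absolute deviation / 0.64 within ~10-gene bins;
fallback median(s)).  An all-constant gene gets d = 0 by convention.

FDR is estimated by permutation: class labels are shuffled uniformly at
random (paired design: random sign flips of the pair differences) with a
fixed seed; for each delta on a 200-point grid over the observed |d| range,
FDR(δ) = median permutation count of |d*| ≥ δ divided by the observed count,
clipped to [0, 1] and made non-increasing in delta by a conservative
step-down pass (each delta inherits the largest raw FDR at or above it).
Selection returns the largest gene set with estimated FDR at or below the
target, split into up/down lists by the sign of d.  Defaults are 200
permutations and a single symmetric delta (no asymmetric up/down arms); at
the package's problem sizes (~10³ genes, tens of samples) this estimates
FDR stably in well under a second.  Random (rather than strictly balanced)
permutations are used because they remain valid for unequal class sizes,
which is the claudin-low-versus-rest situation; no π₀ correction is applied,
which biases the FDR estimate upward (conservative).

## Centroid predictors

A centroid is the per-gene class mean over training samples on a selected
gene list.  The claudin-low and normal-breast predictors are two-class
Euclidean models: a sample is assigned the class of the nearest centroid.
Missing test entries are skipped and the distance is rescaled by
√(n_model_genes / n_used) so distances stay comparable across samples with
different missingness.  Exact ties go to the negative ("others") class:
claudin-low is the positive finding and a tie should not inflate it.  The
intrinsic (PAM50-style) machinery is the same object with a Spearman metric
— highest rank correlation to a class centroid wins — and published
centroid values can be loaded from JSON; only the classification rule is
implemented here, not the published parameters.  Test matrices are
median-centered/standardized before classification, mirroring the
preprocessing of every training set.  The combined intrinsic call applies
the claudin-low override: any sample the claudin-low predictor flags is
called claudin-low regardless of the primary call.

Binary predictors are evaluated as sensitivity, specificity, PPV and NPV in
percent to one decimal; a zero-denominator ratio is reported as absent, not
as zero.

## Differentiation score

The axis is trained on purified mammary populations — stem (MaSC), luminal
progenitor (pL), mature luminal (mL).  Genes are median-centered across the
pooled training populations, the pL centroid is the origin, and DWD gives
the directions of greatest variation pL→MaSC and pL→mL, each normalised to
sum of squares 1.  Scoring a test cohort assumes it covers the range of
differentiation: genes are median-centered *within the test set* (the
platform-bias correction; test-set-alone rather than pooled with training,
which keeps scoring independent of training-data availability), each sample
is shifted by the pL origin and rescaled to unit length (zero vectors are
left at zero), and the two inner products give projected positions.  The
score is proj_mL − proj_MaSC, so higher scores mean greater differentiation;
the subtraction order is a fixed, documented convention.  Prognostic
dichotomization rank-orders samples and splits them into two equal groups
(odd n: the extra sample joins the low group; ties broken by stable input
order).

### DWD

Distance-weighted discrimination minimises Σ 1/rᵢ + C Σ ξᵢ subject to
rᵢ = yᵢ(w·xᵢ + b) + ξᵢ > 0, ξᵢ ≥ 0, ‖w‖ ≤ 1.  Eliminating the slacks yields
a smooth convex problem with the C¹ loss V(r) = 1/r for r ≥ 1/√C and
2√C − Cr below; because the objective depends on w only through inner
products with the training points, the optimum lies in the span of the data
and is found there (dimension ≤ n_samples) by SLSQP with analytic gradients,
initialised at the mean-difference direction.  The penalty defaults to
C = 100/d̃² with d̃ the median pairwise between-class distance, the
customary scale-invariant choice; the returned normal vector is unit-norm
and oriented from the first class toward the second.  A mean-difference
fallback exists behind a flag (`use_mean_difference`) for quick
approximations; it is never the default and no test relies on it.

## Signatures and clusters

Signature scores are the arithmetic mean of the signature's genes per sample
(signed signatures: mean(up) − mean(down)).  The shipped synthetic
signatures are the generator's own module gene lists; real signature GMTs
are accepted wherever a signature is consumed.  Dendrograms use
average-linkage clustering on 1 − r with r the centered Pearson correlation
(the uncentered variant is not offered; centered is the common default of
the classic clustering tools).  A node's "node correlation" is 1 minus its
merge height, and cluster extraction returns the largest subtree containing
an anchor gene whose node correlation exceeds the threshold (default 0.75),
falling back to the singleton anchor.  Group-mean comparisons use the
two-sided unequal-variance (Welch) t-test — matching R's `t.test` default —
with a pooled-variance flag, or one-way ANOVA for more than two groups.

## Association and survival statistics

2×2 tables: Pearson chi-square with df = 1 and *no* continuity correction by
default — the uncorrected statistic is what reproduces the published
dual-immunofluorescence p-values (0.014; the Yates-corrected value would be
≈ 0.030) — with a correction flag; Fisher's exact test is two-sided by the
probability-mass rule (sum of hypergeometric masses no larger than the
observed table's), the R convention, rather than tail-doubling.
Kaplan-Meier curves carry Greenwood variances; groups are compared by the
log-rank test (df = k − 1), and a cohort with no events returns flat curves
with p = 1 and a warning.  Cox models maximise the partial likelihood with
Breslow tie handling by default (Efron behind a flag) and optional
stratification; hazard ratios are exp(coef) with 95% Wald intervals.
Collinear covariates (e.g. a duplicated column) are rejected up front rather
than producing an unstable fit.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any real platform.  Eight 10-gene modules (luminal, proliferation, basal
keratins, claudin/adhesion, EMT, immune, stromal, stem) plus one HER2 marker
gene sit on a background of 900 null genes; the compact gene space keeps SAM
permutation FDR estimable in seconds while leaving the null fraction (>90%)
realistic.  Subtype module means, in units of the effect size (default 2.0
log2 units): claudin-low has claudin/adhesion and luminal at −1, EMT,
immune, stromal and stem at +1 and proliferation at −0.5; basal-like has
basal keratins and proliferation at +1 and luminal at −0.75 (partial luminal
keratin retention, versus the complete loss in claudin-low); luminal A/B
have luminal +1 with proliferation −0.5/+1; HER2-enriched has the marker
gene high with intermediate luminal and proliferation; normal-breast-like is
stromal/immune-high, proliferation-low.  Gaussian noise has sd 0.5, giving
4σ module shifts at the default effect size.  Tumors receive an additive
convex immune/stromal admixture (default fraction 0.15) emulating normal
-tissue contamination; the cell-line generator forces that fraction to zero
and strips the immune/stromal components from every profile (cultures have
no such contamination), emits no normal-like class, and contains nine
claudin-low lines by default.  The sorted-population generator produces
MaSC/pL/mL (optionally stromal) with luminal means strictly increasing and
stem/EMT decreasing along the hierarchy.

Clinical tables draw triple-negative receptor status with probability 0.85
for claudin-low and basal-like tumors; pCR is Bernoulli with per-subtype
defaults of 38.9% (claudin-low) and 73.3% (basal-like) — the published
neoadjuvant response rates — and 5/15/35/5% for luminal A/B, HER2-enriched
and normal-like (chosen so luminal response is far lower, as observed).
Survival is exponential with per-subtype monthly relapse hazards
(luminal A 0.004; claudin-low 0.0113, i.e. a built-in hazard ratio ≈ 2.8
against luminal A; basal-like and HER2-enriched 0.012; luminal B 0.010),
overall-survival hazards at 0.7× the relapse hazard, and independent uniform
censoring on [12, 120] months.  All randomness flows from a single seed
through tagged child streams, so every generated object is bit-reproducible.

What the generator does *not* emulate: two-colour dye bias or any platform
noise structure, probe-level effects, correlated gene-gene noise within
modules, copy number, batch effects, or covariate-dependent censoring.
Passing tests therefore demonstrate method correctness and end-to-end
recovery under the assumed generative structure — not performance on real
microarray cohorts, where contamination, class imbalance and annotation
error are harsher.

## Problem sizes and determinism

Default analyses use 30 tumors per subtype (180 per cohort), 981 genes, 20
samples per sorted population, 200 SAM permutations, and n = 400 for the
Cox-recovery simulation; at these sizes the full pipeline completes in a few
seconds on one CPU.  Every stage seed is derived deterministically from the
global seed, and rerunning a pipeline configuration reproduces its report
byte for byte.

## Known limitations

* The differentiation-score normalization ("transformed to length 1") is
  interpreted as per-sample unit scaling after the origin shift; rescaling
  the axis instead would change score magnitudes (not orderings).  The
  projection conventions here are fixed and documented rather than matched
  to any external implementation.
* Node correlation is defined as 1 − merge height of the average-linkage
  tree; classic clustering GUIs may report a slightly different node value.
* SAM outputs are method-faithful, not list-identical to any published gene
  list: permutation count and s₀ selection are conventions the original
  analyses did not record.
* The Euclidean predictors assume test data preprocessed like the training
  data; single-sample normalization schemes are out of scope.
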