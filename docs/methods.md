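# Methods

This note documents the statistical models implemented in `methylhet`, the
assumptions behind them, the synthetic-data generator used to exercise
them, and the numerical choices that a user tuning the pipeline should
know about.

## E-loci and epiallele statistics

The unit of analysis is the **e-locus**: a window of four adjacent CpGs
close enough to be phased on a single bisulfite read (default maximum
span 100 bp, the read-length scale on which single-molecule phasing is
possible).  Windows slide one CpG at a time, so consecutive e-loci
overlap; overlapping windows are the superset of any tiling and can be
thinned downstream if desired.  CpGs falling at C/T or G/A SNP sites are
removed before enumeration, and CpGs are collapsed to the plus-strand C
coordinate.

Each read covering all four CpGs exhibits one of the 16 binary
**epiallele** patterns (the 5'-most CpG is the most significant bit).
Reads covering fewer than four of the CpGs are excluded from that
e-locus.  With pattern frequencies p_i = c_i / d (d = read depth):

* **epipolymorphism**  E = 1 − Σ_i p_i², the probability that two
  epialleles sampled at random with replacement differ.  E = 0 iff a
  single pattern is observed; the maximum 15/16 = 0.9375 is attained iff
  all 16 patterns are equiprobable.
* **average methylation**  m = Σ_i p_i · popcount(i)/4, identical to the
  mean of the four per-CpG methylated fractions.

A locus with zero depth in a sample is *missing*, never E = 0: a missing
locus carries no evidence of order, and conflating the two would leak
through the coverage filter.  The plug-in estimator of E is biased
downward by a factor ≈ (1 − 1/d) at depth d; at the default ≥10×
filter this is at most 10% and affects both groups of a contrast equally.

Loci enter the analysis when they have depth ≥ 10 in ≥ 75% of samples
(boundary inclusive: exactly 75% passes).

## Differential epipolymorphism

Per retained locus, epipolymorphism is contrasted between two groups
(tumour vs normal when the labels permit; the sign convention is
tumour − normal).  A locus is called significant only when **both**
criteria hold: |Δ mean epipolymorphism| > 0.1 **and** Benjamini–Hochberg
adjusted p < 0.01.  BH runs over loci with a valid p only; loci with
fewer than two non-missing values in a group are reported with missing p
and excluded from the denominator, since they carry no evidence.
Multi-region samples from one patient are deliberately not collapsed by
default (matching a multi-region analysis in which each region is a
sample); a per-patient-mean mode can be emulated by averaging columns
upstream.

Three test statistics are available.  The default is a **Monte Carlo
permutation test** of the group-mean difference (999 relabelings,
p = (b+1)/(B+1)).  The choice is deliberate: epipolymorphism estimates
are bounded, skewed and heteroskedastic across samples whose depths vary,
and at n ≈ 10 per group both Welch's t and the Wilcoxon rank-sum test are
measurably conservative on such data (empirical false-positive rate
≈ 0.038–0.042 at nominal 0.05), while the permutation test is exactly
calibrated (measured 0.049 over 40,000 null loci).  Welch's t
(`welch_t`) and Wilcoxon (`wilcoxon`) remain available for users who
prefer a parametric or rank-based alternative.  The permutation test
shares one set of relabelings across loci (loci are independent), which
reduces the whole genome scan to a single matrix product, and permutes
the label vector in place so that swapping the two group labels provably
negates every statistic and leaves each p-value unchanged.

Direction sets (higher-in-tumour vs higher-in-normal significant loci)
are then compared for annotation enrichment: a locus is "in" an
annotation (promoter, CpG island — BED, 0-based half-open) when any of
its four CpGs falls inside an interval.  Enrichment uses the two-sided
two-proportion chi-squared test without continuity correction (Yates
optional); if any expected cell is below 1 the implementation warns and
falls back to Fisher's exact test.  Fractions count *loci*, not genes.

## Promoter linkage and nested expression models

Promoters default to TSS −1000/+500 bp, strand-aware and half-open
(configurable; the window is a convention, not an estimate).  Every
(e-locus, gene) pair with at least one CpG in the promoter is tested
independently, and BH runs over pairs.  Genes with raw counts < 5 are
removed first (aggregate rule by default, per-sample optional).
Expression is assumed log2-scaled upstream; the package does not
normalize counts.

Two questions are asked per pair, on the identical pairwise-complete
sample set:

1. *Univariate*: OLS of expression on epipolymorphism (≥ 4 samples,
   non-constant regressor); slope sign summarizes the direction of the
   association.
2. *Nested*: expression ~ methylation vs expression ~ methylation +
   epipolymorphism (≥ 5 samples).  The likelihood-ratio statistic is
   n·ln(RSS_reduced/RSS_full) for one extra parameter.  Its p-value is
   computed from the statistic's **exact finite-sample null
   distribution**: under the Gaussian null the statistic is a monotone
   function of F = (RSS_red − RSS_full)/(RSS_full/(n − 3)) ~ F(1, n−3),
   so the F transform gives the same test with correct size, whereas the
   asymptotic χ²(1) reference over-rejects noticeably at n ≈ 20
   (P(p < 0.05) ≈ 0.075).  A pair whose epipolymorphism is exactly
   collinear with methylation (constant, or |r| = 1) cannot add
   information and is reported with statistic 0, p = 1 and a collinear
   flag.  Adjusted R² of both models is reported as computed (the
   unadjusted R² of the full model is never smaller; the adjusted one may
   dip and is stored anyway).

## Heterogeneity indices

* **Variance selection** keeps ⌈fraction·m⌉ features (default 10%)
  ranked by variance across *tumour* samples only; ties break by genomic
  coordinate then feature id so selection is deterministic.
* **APITH** for a patient with n ≥ 2 tumour samples is the mean of all
  C(n,2) pairwise distances; the default distance is the mean absolute
  beta difference over pairwise-complete features (scale-free per
  feature), with Euclidean optional.  Averaging over pairs makes the
  expectation independent of how many regions were sampled from an
  exchangeable pool.
* **PCAR** = DNA-methylation age / chronological age (the clock itself
  is applied upstream; DNAm age is an input column).  A patient is
  methylation-age *homogeneous* when the maximum relative PCAR
  difference among tumour samples, (max − min)/min, is strictly below
  0.30.  The denominator convention (min) is recorded in output headers.
  A single usable sample is homogeneous by convention and flagged n=1.

## Phylo-epigenetic trees

Sample trees are built by neighbor joining (Saitou–Nei Q-criterion, via
dendropy) on methylation distance matrices (Euclidean, Manhattan or
1 − Pearson, pairwise-complete with ≥ 10 shared features required per
pair).  On additive matrices NJ reproduces the generating topology and
branch lengths exactly; on noisy matrices any negative estimated branch
is clamped to zero with the deficit pushed into the adjacent branches so
paths through the node are approximately preserved.  The artificial
degree-2 root dendropy places on the unrooted NJ tree is collapsed, so
for three taxa the pendant branch lengths equal the three-point formulas.

Tree concordance uses the unrooted **Robinson–Foulds** distance (count of
non-trivial bipartitions present in exactly one tree), normalized by the
binary-tree maximum 2(n − 3).  Copy-number trees are consumed as Newick;
RF is computed on unrooted topologies — rooting on a normal sample would
only add a shared trivial split and is not required.

## Reference-free deconvolution

Bulk beta values D (features × samples, typically the top-variance DMCs
in tumour) are factorized as D ≈ T·A with T ∈ [0,1]^{m×k} (latent
methylation components, interpreted as cell-type methylomes) and A ≥ 0
with columns on the probability simplex (per-sample proportions), by
minimizing

    ‖D − T·A‖²_F + λ·Σ T(1 − T)

The λ-term pushes component methylomes toward the biologically expected
0/1 poles.  Optimization alternates:

* **A-step**: simplex-projected gradient descent on the convex quadratic,
  all columns jointly, step 1/L with L the largest eigenvalue of TᵀT
  (valid for masked columns too, since their Hessians are dominated by
  TᵀT); monotone by construction.
* **T-step**: exact per-entry minimization of the scalar quadratic over
  [0,1].  For λ larger than the local curvature the quadratic is concave,
  so the interior stationary point and both bounds are all evaluated and
  the minimizer chosen; every coordinate step is a global scalar
  minimizer and never increases the objective.

The objective is asserted non-increasing at every alternating step
(tolerance 1e-9 relative); a violation aborts the run.  Ten random
restarts (T ~ Uniform(0,1), A columns ~ Dirichlet(1)) guard against local
minima; the best final objective wins; everything is deterministic given
the seed.  Component order is arbitrary: comparisons against a known
truth first resolve the permutation by Hungarian assignment on proportion
correlations.

Model selection masks a random 10% of entries per fold, fits on the rest
(masked objective) and scores reconstruction RMSE on the hidden entries;
the (k, λ) pair minimizing mean RMSE wins, ties going to smaller k then
larger λ.  Held-out RMSE only penalizes superfluous components when the
data carry noise for them to overfit: on noise-free synthetic mixtures
every k ≥ k_true reconstructs the low-rank matrix and the curve is flat,
so the selection benchmark uses mixtures with entry noise (SD 0.05).
Including λ = 0 in the selection grid matters for the same reason — a
strong pole penalty biases the small-k fits and lets extra components
absorb that bias, shifting the CV minimum upward.

Components are interpreted by Pearson correlation against reference
methylomes on ≥ 100 shared features (BH-adjusted two-sided tests; no
call above adjusted p 0.05) plus joint average-linkage clustering on
1 − correlation.  Proportion rows are compared across binary clinical
labels with two-sided Wilcoxon rank-sum tests, BH-adjusted across labels.

## Synthetic data

The generator emulates a two-group multi-region renal-cancer study: 18
patients with several tumour regions each plus normal kidney samples
(the default layout yields 136 samples), planted disorder differences,
expression coupled to promoter methylation and disorder, near-binary
cell-type mixtures, and additive trees.

* Non-differential e-loci share one pattern-probability vector between
  groups, drawn from a sparse symmetric Dirichlet (concentration 0.5) —
  most draws are dominated by one or two patterns, emulating the mostly
  concordant loci of real methylomes while keeping disorder estimates
  non-degenerate.
* Differential e-loci (default fraction 0.2, matching the observed
  ~28k/138k rate) get a near-uniform Dirichlet vector (concentration 10)
  in one group — half the time the tumour group — and an ordered vector
  with concentration 100 on an all-methylated or all-unmethylated pole
  (50/50) in the other.  The truth table records the realized
  epipolymorphism of each group's vector.
* Read depth is negative-binomial (mean 30, dispersion 5); zero-depth
  loci are emitted as missing, which is what the ≥75%/≥10× filter acts
  on.
* Expression: y = b0 + β_meth·meth + β_epi·epi + N(0, σ), one gene per
  e-locus (defaults β_meth = −2, β_epi = −1, σ = 0.5: promoter
  methylation and disorder both repressive, as dominates empirically).
  The `residual_sd` effect scale re-expresses β_epi per gene in units of
  σ per SD of epi *orthogonal to methylation* — the incremental signal a
  nested test measures.
* Mixtures: component methylomes near the 0/1 poles (Beta(1,30) spread),
  Dirichlet proportions, optional Gaussian entry noise, clipped to
  [0,1].
* Trees: grown by attaching leaves to uniformly chosen edges with
  positive branch lengths, so path lengths are additive by construction;
  features evolve by Brownian motion along branches.

What the generator does **not** emulate: realistic genome coordinates or
sequence context (loci sit on ordered synthetic chromosomes), linkage
between neighbouring e-loci, purity gradients, batch effects, or
count-level expression noise (expression is simulated directly on the
log2 scale).  Passing tests therefore demonstrate correctness of the
statistics and algorithms under the stated model, not robustness to
every artefact of real Epic-seq data.

Default problem sizes in the test-suite and acceptance computations
(2,000 loci, 10–47 samples, 500×30 mixtures, trees up to 12 leaves) are
chosen as the smallest sizes at which the statistical properties are
measurable with tight Monte Carlo error; all generators scale to larger
designs through `SimulationConfig`.

## Numerical conventions

* Coordinates are 0-based half-open internally; the 1-based CpG-report
  dialect is shifted on input; BED and promoter intervals are half-open.
* All randomness flows from one root seed through named substreams
  (`simulate.substream`), so stages can be re-run independently and
  byte-identically.
* Every output table carries `# key: value` header lines with the tool
  version, seed and effective thresholds; `run-all` snapshots the full
  effective configuration as YAML.
* Ties in variance selection break by coordinate then id; ties in model
  selection by smaller k then larger λ; both deterministic.

## Known limitations

* The epipolymorphism estimator is not debiased; contrasts at very low
  or very unequal depths inherit the (1 − 1/d) bias differentially.
* The permutation test's smallest attainable p is 1/(B+1); with the
  default B = 999 and BH over tens of thousands of loci, adjusted
  significance below ~1e-3·m/rank is not resolvable — raise
  `n_permutations` for finer resolution.
* Nested models assume Gaussian residuals on the log2 scale and test one
  e-locus at a time; they quantify association, not causation, and
  methylation and disorder remain partially confounded by construction.
* The NMF objective is non-convex; restarts mitigate but do not remove
  local-minimum risk, and component identifiability relies on the
  simplex constraint plus pole penalty.
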