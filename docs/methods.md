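# Methods

## Scope and model

`mrmrnet` implements a two-group expression analysis for feature-by-sample
log2 intensity matrices carrying both protein-coding (mRNA) and long
noncoding (lncRNA) probes: mutual-information-based mRMR feature ranking,
fold-change summaries with hierarchical clustering, 2^−ΔΔCt qPCR
arithmetic, hypergeometric gene-set over-representation, and a
thresholded Pearson lncRNA–mRNA co-expression network. The statistical
model is deliberately simple: expression values are treated as
exchangeable continuous measurements per feature; the only distributional
assumption anywhere is in the synthetic generator (Gaussian on the log2
scale, the standard working model for microarray intensities).

## mRMR ranking

**Discretization.** Mutual information on continuous intensities requires
binning. Each feature is mapped to three states around its own mean:
−1 below μ − t·σ, +1 above μ + t·σ, 0 between, with σ the sample standard
deviation (ddof = 1) and t = 0.5 by default — the convention of the mRMR
literature for expression data. Constant features (σ = 0) map entirely to
state 0 and therefore carry zero relevance. `t` is exposed: larger values
push more samples into the middle state and lower every MI estimate.

**Estimator.** Plug-in (empirical frequency) mutual information in bits
(log base 2; only rankings matter, so the base is a pure convention).
0·log 0 ≡ 0; tiny negative round-off is clamped to 0. The hot path
(one vector against thousands of candidates) is vectorized over joint
count tables; it is exactly the same estimator as the scalar function and
tests assert so.

**Selection.** Greedy: round 1 takes argmax D; round h > 1 maximizes
D − R (MID) or D/(R + ε) with ε = 10⁻¹² (MIQ). MID is the default; both
variants are standard and which a given study used is often unreported,
so both are first-class. R of the first pick is 0 by convention. All ties
break to the earliest feature in input order, making every ranking
deterministic and reproducible. mRNAs and lncRNAs are ranked in one joint
candidate pool by default; callers wanting per-biotype tables can subset
the matrix with `ExpressionMatrix.subset_biotype` first.

**Pre-selection.** How a study reduces tens of thousands of probes to an
mRMR candidate pool varies; `filter_features` provides a parameterized
variance filter (minimum variance, then top-N by variance) rather than a
hard-coded rule.

## Normalization

`quantile_normalize` replaces each sample's values by the across-sample
mean of sorted values at the sample's own ranks; ties receive the average
of the reference values at the tied ranks (via average ranks and linear
interpolation). On tie-free data the map is exactly idempotent. With
within-sample ties, tie-averaging means a renormalization can shift the
averaged values slightly — the same behavior as the widely used
implementations of this procedure. Normalization is optional: validation
and all downstream stages accept un-normalized matrices.

Missing values are rejected rather than imputed: imputation would change
the discretization and MI estimates in ways that cannot be validated.

## Differential expression and clustering

log2 fold change is exactly mean(case) − mean(control) per feature; the
direction call uses |log2FC| ≥ 1 by default (one doubling), a convention
rather than a test. Hierarchical clustering uses distance 1 − Pearson r
and average linkage (UPGMA), the usual microarray heatmap pairing;
constant vectors have undefined correlation and are assigned distance 1
to everything, with a warning. Merge heights are non-decreasing because
average linkage is monotone. Dendrograms serialize as a JSON merge list
or Newick.

## 2^−ΔΔCt

Samples are unpaired case/control, so ΔΔCt is the difference of
group means of per-sample ΔCt (not per-sample pairing). With noise-free
Ct values the computation is an algebraic identity: any planted fold F
is recovered exactly. With measurement noise the estimator
2^−mean(ΔΔCt) is the geometric-mean fold and carries a small upward
bias of order (σ ln 2)²/2, well inside the ±20% envelope asserted at
σ = 0.2 cycles and n = 15 per group.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) for overlap k between the mapped
gene list and a category, against the declared annotation universe
(`scipy.stats.hypergeom` supplies the distribution). EASE mode —
DAVID's conservative modified Fisher test — substitutes k − 1 (floored at
0), so singleton overlaps are never significant. −lg P is −log₁₀ p;
p is floored at 10⁻³⁰⁰ to keep it finite. The percent column divides by
the *mapped* list size (genes found in the universe), matching the DAVID
reporting convention. Benjamini–Hochberg FDR is computed across all
categories with non-zero overlap before any −lg P filtering or top-k
truncation. No GO-graph propagation is performed; categories are taken
as given in the GMT.

## Co-expression network

Only cross-biotype (lncRNA, mRNA) pairs are tested, yielding a bipartite
graph. The default mode thresholds |r| ≥ 0.8 — the stated coefficient
cutoff with no mention of sign handling is common in this literature, so
absolute is the default and a signed mode (r ≥ threshold) is offered; the
mode is recorded on the network object. The boundary is inclusive, with a
10⁻¹² guard so r computed exactly at the threshold is kept despite float
round-off. No correlation p-value filter is applied: the coefficient
threshold is the criterion. Constant features are skipped with a warning.
Nodes are probe/feature ids; collapsing probes to gene symbols is
upstream of this module.

## Synthetic data generator

The generator emulates the study design the pipeline targets: two
classes (default 15 + 15), a few thousand probes with lncRNA fraction
0.54 (the approximate lncRNA share of a whole-transcriptome lncRNA+mRNA
array), feature baselines ~ N(8, 1.5²) log2 units, residual noise
N(0, σ²) with σ = 1 by default.

- *Informative* features get opposite half-shifts of ±effect/2 per group
  (default effect 2 log2 units), so the group-mean difference equals the
  effect size with random sign.
- *Redundant* features are a source feature plus N(0, (0.2σ)²)
  perturbation, giving sample correlation > 0.95 with the source —
  controllable redundancy for the mRMR penalty.
- *Co-expressed* lncRNA–mRNA pairs share a latent factor:
  x = √ρ·z + √(1−ρ)·e gives pair correlation exactly ρ (default 0.9).
  Pairs are carved from the noise block, so they stay class-null.
- Feature roles are scattered over random row positions; ids are
  numbered within biotype (LNC_0001…, MRNA_0001…).

Ct tables plant a fold F by shifting the target's case Ct down by
log₂ F against a flat reference gene; Gaussian cycle noise is optional.
Annotation collections plant enrichment by drawing 60% of a planted
category's members from the informative set.

Identical config + seed is bit-identical (single `numpy` Generator).

**What passing tests do and do not show.** The generator produces
independent Gaussian features with clean planted structure. It does not
model probe-level artifacts, batch effects, dye bias, heavy-tailed
intensities, or correlated noise — so recovery rates measured here are
upper bounds on what identical settings would achieve on real arrays,
and the exact gene lists of any particular study are not reproducible
from synthetic data.

## Numerical choices and problem sizes

- MI non-negativity: values are clamped at 0 below a 10⁻¹² tolerance.
- MIQ division guard ε = 10⁻¹².
- All stochastic checks fix their seeds; aggregate recovery criteria are
  computed over 20–50 seeds at the default design (e.g. ≥ 90% of 20
  planted features in the mRMR top-40 of 2,000 candidates; network
  sensitivity ≥ 95% with false-edge rate ≤ 0.01 at |r| ≥ 0.8 and
  n = 30). These sizes keep the full suite and the acceptance script at
  a few seconds each while leaving comfortable statistical margins.
- Exactness checks use independent oracles: rational-arithmetic MI over
  all 3×3 joint tables with n ≤ 8, a per-round brute-force mRMR rescan,
  exhaustive hypergeometric draw enumeration for universes ≤ 12, an
  all-pairs correlation double loop, and a naive average-linkage
  agglomerator.

## Known limitations

- The plug-in MI estimator is biased upward at small n; rankings are
  robust to this but absolute D values should not be over-interpreted.
- No moderated-variance differential test (limma/DESeq-style) is
  provided; fold change here is descriptive.
- Enrichment treats categories as flat sets; GO hierarchy and KEGG
  topology are out of scope.
- The network reports degrees only; centrality and module detection are
  out of scope.
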