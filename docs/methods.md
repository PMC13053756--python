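# Methods

## Overview

`epigrn` infers a gene-regulatory network (GRN) in two stages: an
*epigenomic prior network* is estimated first, from motif-rank /
epigenomic-signal association; a tree-ensemble regression then refines
each gene's candidate-regulator set against expression data.  This
note documents the models, the statistical machinery, the defaults and
the design choices that were genuinely open.

## Epigenomic prior network

### Association statistics

For motif *l* and sample *j* the association is computed over the
regions with data in that sample, using *match closeness* (the negated
rank, so larger = better sequence match) as the score:

* **MLC** (binary signal, e.g. peak presence): Somers' D between
  closeness and the 0/1 signal, computed through the mid-rank
  Mann–Whitney identity, so it equals pairwise concordance
  (ties contribute 0) exactly.  AUC = (D + 1)/2.
* **MethCorTarget** (DNAme rates): Spearman ρ with mid-ranks for
  ties.  The statistic keeps its sign (binding that protects from
  methylation shows up as negative ρ); the test is two-sided, which is
  the same test as one on |ρ|.

Either statistic is converted to z = atanh(stat)·√(R_used − 3) with a
two-sided Gaussian p-value.  The √(R−3) variance is the classical one
for ρ and is applied to D as well, on the assumption that the
transform is close enough to variance-stabilising for a
concordance-type statistic.  |stat| = 1 maps to p = 0 with an explicit
infinite-z flag; undefined statistics (single-class labels, constant
signal) are skipped for that (motif, sample) pair rather than coerced
to 0.

### Retention and edge construction

A motif is retained in sample *j* when p < α (default α = 0.1, a
deliberately permissive screen: the regression stage removes false
positives).  Across samples, the default rule is a strict majority of
the samples in which the statistic was defined; an integer
`at_least_k` rule is available for designs with few samples.

A retained motif is *matched* to the regions ranked within the best
`top_frac` fraction (default 0.05, ceiling rule).  The match cutoff is
this package's parameterisation — only the idea of "motif-matched
regions" is inherited, not a numeric threshold.  Regions are assigned
to the gene with the nearest promoter; the distance of a TSS to a
half-open interval [start, end) is max(start − TSS, TSS − end, 0), an
assignment is kept when the distance is below `max_dist` (default
5000 bp), and exact ties break by lexicographic gene id.  Edges are
(TF(l), gene(r)) over a retained motif's matched, assigned regions; a
TF with several motifs contributes the union of their edges.

### Region-level methylation aggregation

Region rates are Σ methylated / Σ total over the CpGs inside the
region per sample; entries with fewer than `min_reads` (default 10)
total reads are flagged uncovered.  For MethCorTarget, a region enters
the correlations only when covered in at least `min_covered_samples`
samples (default 3, switchable to a majority rule).  Coordinates are
0-based half-open throughout; Bismark's 1-based positions are shifted
on read, and the redundant percent column is ignored (counts win, with
a warning when they disagree).

## GRN inference

Expression is CPM-normalised (each cell scaled to 10⁶ total counts);
tree ensembles are invariant to monotone per-gene transforms, so no
further transformation is applied by default (log1p is available).
Each target is regressed on its expressed prior candidates with
xgboost gradient-boosted trees — defaults 200 trees, depth 4,
learning rate 0.1, subsample 0.8, recorded in every fit.  Edge weight
is total split gain (exactly 0 for candidates never split on).
Per-target seeds derive deterministically from the model seed, so a
GRN fit is reproducible bit-for-bit.

### Threshold calibration

On simulations with known truth, for each grid cell (n cells,
p candidates) and replicate, the gain cutoff maximising Youden's
J = TPR − FPR against the true parent sets is recorded (maximising J
and maximising the AUC of the binarised predictor are the same
criterion, since that AUC is (J + 1)/2).  J is piecewise constant
between observed gains, so the midpoint of the optimal interval is
reported.  The table value used for selection is the **lower
quartile** of the per-replicate optima — the quartile is taken over
thresholds, not over AUC values (a quartile of AUC is not a
threshold), trading extra false positives for fewer false negatives,
which downstream aggregation tolerates.  Lookup for off-grid (n, p)
snaps to the nearest grid point in log-space.

## Evaluation

* **Edge-ranking AUC**: mid-rank AUC of gain scores for true vs
  non-true edges over an explicit candidate universe.  When comparing
  prior-constrained runs against a full-candidate baseline, all runs
  are scored over the *same* universe (all TF × target pairs), with
  edges outside a run's candidate set scored 0 — otherwise the
  comparison is confounded by the different negative sets.
* **Ablation**: the observed R² is from an OLS fit
  (intercept + selected regulators, same samples as the fit; no
  held-out split, so observed and null are computed under an identical
  protocol).  The null repeats select-then-fit on p TFs drawn
  uniformly from all TFs in the prior, excluding the target
  (100 draws by default); z = (R² − mean R̃²)/sd R̃².  A one-sided
  one-sample t-test (greater) summarises the z-scores genome-wide.
* **Overlap odds ratio**: 2×2 classification of a universe by
  membership in two edge sets; Woolf logit 95% CI; two-sided Fisher
  exact p.  Zero cells get the Haldane 0.5 correction for the OR/CI
  (flagged); the p-value always uses the uncorrected table.

## Differential regulation

Per TF, gains over its prior targets fitted in both conditions are
compared with a **paired t-test by target** (pairing by target is this
package's reading; candidates fitted but never split on contribute
gain 0, keeping the paired sample complete).  Gains enter the test on
the **log1p scale**: raw split gains scale with each target's
expression variance, which makes the paired differences heavy-tailed
and the t-test miscalibrated in the far tail (observed false-positive
fractions well below nominal, and poor power); log1p preserves zeros
and direction and restores near-nominal behaviour.  Benjamini–Hochberg
adjustment runs across TFs; direction is `hyper` (stronger in
condition A) or `hypo` by the sign of the mean log-scale difference.
The differential network keeps significant TFs, their selected targets
with a non-`ns` differential-expression label (labels are an input —
DE testing itself is out of scope), and the selected GRN edges between
them, per condition.

## Edge robustness

Pr(E|D) is estimated with the Bayesian bootstrap: flat
Dirichlet(1,…,1) weights over cells (rescaled to mean 1), a weighted
refit per replicate, and the score is the fraction of replicates in
which the candidate's gain exceeds the threshold.  The ensemble seed
is held fixed across replicates so that all between-replicate
variation comes from the weights; with equal weights every replicate
is identical and scores are exactly 0 or 1.  Default B = 200 for
desk-scale use; B is a parameter (the procedure is linear in B).
The classical resample-with-replacement bootstrap is deliberately not
offered: duplicated rows interact badly with tree fitting.

## Synthetic data

The generator emulates the statistical structure the pipeline needs,
not any particular organism:

* **Network**: TFs in a fixed order; each gene draws Poisson-many
  parents (mean 2) from earlier TFs, so the graph is acyclic by
  construction; each edge is an activator with probability 0.75.
  Defaults (20 TFs, 80 targets) give a ~100-gene network; benchmark
  runs use 300 cells, mirroring the simulated-profile count used for
  the method's validation.
* **Expression**: root TFs are lognormal (log-mean 0.5, log-sd 0.8);
  a downstream gene's mean is (v/λ)·Π Hill terms over its parents
  (x^h/(K^h + x^h) for activators, K^h/(K^h + x^h) for repressors;
  h = 2, K = 1, v = 2, λ = 1), times lognormal cell noise
  (log-sd 0.3); Poisson counts at a 10⁶ library depth, so CPM values
  sit close to the underlying rates.  This is a steady-state Hill
  DAG model — a deliberate simplification of full stochastic
  reaction-kinetics simulators that preserves what the benchmark
  needs: nonlinear, signed parent→child dependence.  It has no
  feedback loops, no dropout and no cell-type mixture structure, so
  passing benchmarks say nothing about those regimes.
* **Priors**: true parents plus `n_decoys` TFs drawn uniformly from
  the non-parents (capped with a warning when the pool runs out).
* **Epigenome**: regions on one synthetic chromosome, spaced 20 kb so
  that each region's own gene (present for 70% of regions, TSS 300 bp
  downstream) is the only promoter within 5 kb.  Motif scores are
  standard normal; ranks are their descending order.  For active
  motifs the signal tracks the mean standardised score of the active
  set — methylation falls (clip to [0, 1], Gaussian noise sd 0.1) or
  peak log-odds rise with better matches; inactive motifs are
  independent of the signal, giving an exact null.  The planted truth
  is each active motif's matched (top 5%), gene-assigned regions, so
  it is recoverable exactly by the prior constructors when the effect
  is strong.

Every generator is a pure function of (spec, seed).

## Problem sizes and runtime

The test-suite benchmarks use networks of ~100–250 genes, 300 cells,
5–10 replicates, and lighter ensembles (50–100 trees) than the
package default — the comparisons being made (prior vs baseline,
informative vs randomised prior, condition A vs B) are unaffected by
ensemble size well before 200 trees, and every fit records its
hyperparameters.  The acceptance script runs the same computations at
5 replicates and completes in a few minutes on one core.

## Known limitations

* The Fisher-transform null for Somers' D is an approximation; its
  accuracy degrades for very small R (the code refuses R_used < 4 and
  the calibration test covers R = 500).
* Prior construction tests each motif marginally; co-occurring motifs
  are not deconvolved, and a motif can be retained through correlation
  with a truly active one (the regression stage is the corrective).
* The threshold table transfers across datasets only to the extent
  that gain scales match; gains scale with expression variance, so
  thresholds calibrated on CPM data should be applied to CPM data.
* Robustness scores underestimate Pr(E|D) for collinear regulators:
  trees pick one of an exchangeable pair per refit, splitting the
  score mass between them.
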