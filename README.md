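# epigrn

Gene-regulatory network (GRN) inference from single-cell expression
data, constrained by an **epigenomic prior network** built from
DNA-methylation or chromatin signal at TF-motif-matched regions.

## The problem

A network inferred from expression data alone is a co-expression
network: it cannot distinguish a transcription factor (TF) that
physically regulates a gene from one that merely co-varies with it.
`epigrn` addresses this with a two-stage procedure:

1. **Epigenomic prior network.** For every TF motif *l* with a
   match-closeness ranking x<sub>l</sub>(r) over candidate
   cis-regulatory regions r ∈ {1,…,R}, test per sample *j* whether the
   epigenomic signal y<sub>j</sub>(r) at those regions tracks the
   motif's match quality:
   * binary chromatin signal (peaks): Somers' D, with
     AUC = (D + 1)/2 (the *MLC* method);
   * region-average DNAme rates in [0, 1]: Spearman ρ
     (the *MethCorTarget* method).

   Either statistic is Fisher-transformed,
   z = atanh(stat)·√(R − 3), and a motif is retained per sample at
   p < 0.1, aggregated over samples by a majority rule.  Retained
   motifs contribute candidate edges TF → gene for genes whose
   promoter lies within 5 kb of the motif's best-matched regions.
   The result is a *target-specific* candidate-regulator set
   PA_prior(i) of a few tens of TFs per gene.

2. **Prior-constrained regression.** Each target gene's expression is
   modelled as x<sub>i</sub> = f(x<sub>PA_prior(i)</sub>, e<sub>i</sub>)
   with gradient-boosted tree ensembles (xgboost).  The total
   split-gain importance of each candidate TF is the edge weight; an
   edge is selected when its gain exceeds a threshold calibrated on
   simulations with known ground truth (maximum Youden's J, lower
   quartile across replicates, indexed by sample size n and candidate
   count p).

Shrinking the candidate set from hundreds of TFs to target-specific
tens is what drives the accuracy gain, and the package ships a
kinetic simulator (signed DAG + Hill activation/repression + Poisson
counts) so the whole claim is testable without any external data.

Also included: an **ablation study** (is the prior informative? R² of
the selected regulators vs. a null over random candidate sets, one
z-score per gene), **differential regulation** between two conditions
(paired t-test on importance gains per TF, Benjamini–Hochberg FDR),
and **edge robustness** Pr(E|D) via the Bayesian bootstrap
(flat-Dirichlet sample weights, fraction of refits in which an edge's
gain clears the threshold).

## Worked example

```python
import epigrn as eg

# a 100-gene ground-truth network observed in 300 cells
spec = eg.SimulationSpec(n_tf=20, n_targets=80, seed=1)
net  = eg.simulate_network(spec)
expr = eg.cpm_normalize(eg.simulate_expression(net, n_cells=300, spec=spec))

# target-specific prior: true parents plus 5 decoy TFs per gene
prior = eg.simulate_prior(net, n_decoys=5, seed=1)

res = eg.GRNModel(expr, prior, seed=1).fit()
print(res.summary())

truth = {e for e in net.edge_set() if e[1] in set(net.target_ids)}
universe = {(tf, t) for tf in net.tf_ids for t in net.target_ids}
print("edge-ranking AUC:", round(eg.grn_auc(res.edges, truth, universe), 3))
```

Output:

```
Gene-regulatory network fit
========================================
targets fitted:      80
targets skipped:     0
candidate edges:     564
selected edges:      564
mean q per target:   7.05
samples (n):         300
seed:                1
edge-ranking AUC: 0.896
```

The 564 candidate edges are the prior's parent sets (true parents +
5 decoys each); with no threshold table every positive-gain edge is
marked selected, and the gain ranking places the true edges well ahead
of the decoys (AUC 0.896 against the 1600-pair TF × target universe,
unscored pairs counting 0).  Swapping the prior for the full candidate
set (`eg.full_candidate_prior(net.tf_ids, net.target_ids)`) drops the
AUC to 0.665 on the same data — the measurable value of a
target-specific prior.

The same objects drive the command line:

```bash
epigrn simulate --what all --seed 1 --out sim/
epigrn prior-methcor --rankings sim/rankings.tsv --signal sim/signal.tsv \
    --regions sim/regions.bed --tss sim/tss.tsv --out prior/
epigrn infer-grn --expr sim/expression.tsv --prior prior/prior.tsv \
    --seed 1 --out grn/
```

Every run writes a `manifest.json` (config echo, version, input
checksums) and identical configs reproduce byte-identical tables.

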