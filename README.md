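# clam — trans-omics gene-module detection with interaction priors

`clam` finds co-expressed gene modules by integrating several omics
expression layers (e.g. RNA-seq and proteomics of the same cohort) that may
measure **different genes and different samples**, and by folding **known
molecular interactions** (TF→target, miRNA→target, protein–protein
interactions, pathway membership) into the clustering. It also ships the
module-evaluation metrics used to benchmark module detectors and a
module-based survival analysis that asks whether the *co-expression level*
of a module — not the expression of any single gene — predicts patient
survival.

## The method

**1. Trans-omics neighborhood graph.** In each layer, every gene is linked
to its *k* (default 10) most similar genes; similarity is |Pearson r| by
default (anti-correlated genes are admitted as neighbors; the sign is kept
for later orientation), optionally 1/(1+d) Euclidean or binned mutual
information. Weights are normalised similarities,

    w_xy = S_xy / Σ_{z∈KNN(x)} S_xz ,   Σ_y w_xy = 1 .

The per-layer graphs are fused: a gene measured in *m* layers carries its
*m*·*k* neighbors with weights divided by its own *m*, and duplicated
(gene, neighbor) pairs are merged by summing — recurring neighbors gain
weight. No gene or sample matching across layers is required.

**2. Co-regulatory prior.** For each gene *g₁* with *n₁* miRNA regulators,
*n₂* TF regulators and *n₃* PPI partners (pathways count as additional
TF-like anchors by default), a neighbor reached through a shared regulator
that targets *n₄* of *g₁*'s neighbors scores `1/(n₁+n₂+n₃) · 1/n₄`; a
direct PPI partner scores `1/(n₁+n₂+n₃)`; multiple connecting paths sum;
unconnected neighbors score 0. A softmax turns the scores into prior
probabilities and each edge weight becomes `w_xy · prior_xy`
(renormalised), so functionally supported neighbors gain weight.

**3. Local approximation of membership.** Each gene's density is the mean
similarity to its neighbors. Genes denser than all their neighbors become
cluster centers; low-density genes (below the global mean density by
default) become outlier prototypes. With *M* centers every gene carries a
membership vector over *M* clusters plus an outlier slot; centers and
outliers are one-hot and fixed, the rest start at 1/(M+1) and are updated
synchronously by

    p_x ← Σ_{y∈KNN(x)} w_xy p_y

until convergence of E = Σ_x‖p_x − Σ_y w_xy p_y‖². Genes go to their
argmax slot: a module per center, or the outlier set.

**Evaluation** (precision, recall, relevance, recovery against known
module collections, each normalised by the mean over permuted known
modules, summarised by their harmonic mean, with a module-level k-fold CV
harness) and **module-based survival analysis** (z-score each module gene,
flip anti-correlated members, take the per-patient standard deviation σᵢ
of the aligned z-scores — low σ = tight co-expression — split patients at
the median of σ and compare survival curves with the log-rank test, against
mean-expression and single-gene baselines) complete the pipeline.

## Worked example

Everything below is generated — no external data needed. The synthetic
study plants 5 co-expression modules of 20 genes (within-module |r| ≈ 0.8,
hub-structured) on a 200-gene background, split over two omics layers with
partial gene/sample overlap, plus a TF covering half of each module and
survival times whose hazard rises with the co-expression σ of module 1.

```python
from clam import CLAM, SimulationConfig, generate, truth_comparison
from clam.survival import ModuleSurvival

study = generate(SimulationConfig(seed=1))
results = CLAM(study.datasets, study.interactions).fit()
print(results.summary())
```

```
CLAM module detection results
==============================================
datasets:          2 (omics_1, omics_2)
objects clustered: 300
k (per dataset):   10
similarity:        pearson (|r|)
prior:             on
cluster centers:   6
modules found:     6
outlier genes:     200
iterations:        191 (converged)
final objective E: 28.9091
----------------------------------------------
module sizes:
  module_1          20
  module_2          20
  module_3           3
  module_4          17
  module_5          20
  module_6          20
```

The five planted modules are recovered almost exactly (one split into a
17+3 pair) and all 200 background genes land in the outlier set:

```python
print(truth_comparison(results.modules, study.truth))
# {'ari': 0.998, 'relevance': 0.833, 'recovery': 0.970}
```

The survival screen finds the causal module through its co-expression σ
(sd mode) while the mean-expression comparison sees nothing:

```python
screen = ModuleSurvival(results.modules, study.datasets[0], study.clinical).fit()
print(screen.summary())
# module_1   sd     chi2 25.2   p 5.1e-07   p_adj 3.1e-06
# module_1   mean   chi2 0.09   p 0.77      ...
```

The same pipeline runs from the shell:

```bash
clam simulate --seed 1 --out-dir fixtures/
clam cluster --expr fixtures/expr_omics_1.tsv --expr fixtures/expr_omics_2.tsv \
             --tf fixtures/tf_edges.tsv --k 10 --out modules.gmt
clam evaluate --observed modules.gmt --known fixtures/truth_modules.gmt \
              --permutations 500 --seed 1 --out report.json
clam survival --modules modules.gmt --expr fixtures/expr_omics_1.tsv \
              --clinical fixtures/clinical.tsv --mode sd --out survival.tsv
clam pipeline --config run.yaml --out-dir results/   # chains all stages
```

`--k 5:15` sweeps the neighbor count and reports the module count per k.

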