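# Methods

This note records the model, the numerical choices and the open design
decisions behind the package, and what the synthetic benchmark does and
does not demonstrate.

## Model and procedure

### Neighborhood construction

Each omics layer is a genes × samples matrix. Similarity between two
fully-imputed profiles is, by default, the absolute Pearson correlation:
strongly anti-correlated genes are genuine module candidates (the survival
stage explicitly orients them), so |r| admits them as neighbors while the
sign of r is retained separately. A `positive r only` mode
(`absolute_corr=False`) clips negative correlations to zero instead.
Alternatives: `1/(1+d)` on Euclidean distance, and mutual information on
equal-frequency-binned profiles with `max(2, floor(sqrt(n_samples)))`
bins (the estimator is unspecified in the source method; equal-frequency
binning is the parameter-free default).

Per layer, each gene keeps its `min(k, n−1)` most similar genes
(ties at the cut broken by lexicographic gene id, for determinism), with
weights `w_xy = S_xy / Σ_z S_xz`. The neighbor relation is directed and
never symmetrised. Neighbors with similarity exactly 0 in an otherwise
positive list are dropped; a gene whose entire list is non-positive gets
uniform weights with a warning.

Fusion: the object set is the union over layers; a gene present in *m*
layers has each incoming weight divided by its own *m* (not a global *m*),
and duplicate (gene, neighbor) pairs merge by summing weights. Weight mass
is conserved exactly. The **retained similarity** of a merged edge is the
plain mean over the layers in which the edge occurs. The 1/m division is
probability bookkeeping and must not be applied to similarities: halving
the similarity of single-layer edges makes densities incomparable between
genes measured in different numbers of layers, which measurably distorts
center/outlier detection (single-layer genes become spurious density
maxima).

By default identical gene identifiers across layers are merged into one
object (a gene in *m* layers then has up to *m*·*k* neighbors). Because
cross-layer identifier collision can be unintended, `merge_identifiers=False`
namespaces every object as `<gene>@<layer>`.

### Co-regulatory prior

For gene g₁: n₁ = miRNAs targeting it, n₂ = TFs targeting it, n₃ = direct
PPI partners; with `include_pathways` (default on) each pathway containing
g₁ counts as one more TF-like anchor. Every anchor edge carries
`1/(n₁+n₂+n₃)`. A shared regulator (or pathway) that reaches n₄ of g₁'s
graph neighbors passes `1/n₄` of its mass to each; a direct PPI partner
receives the full anchor mass. Contributions over distinct connecting
paths **sum** (the source formula scores a single path; summation is the
natural multigraph extension and keeps every score ≤ 1). Neighbors outside
the co-regulatory network score 0; a gene with no anchors scores all
neighbors 0.

Scores become a prior over the neighbor list through a softmax
`p_i ∝ exp(c_i/τ)` with temperature τ = 1 by default (the source describes
"softmax regression" without features or training data; this package reads
it as a softmax transform — the only parameter-free interpretation).
Weights become `w·p` and are renormalised per gene by default so that
membership propagation stays on the probability simplex; the
unrenormalised variant is available (`renormalize=False`), in which case
each updated membership vector is projected back to the simplex by L1
normalisation (required for well-posedness). With an empty interaction
database the softmax of all-zero scores is uniform and the graph is
unchanged — the prior can never hurt by absence.

### Module identification

Density of a gene = mean retained similarity over its (fused) neighbor
list. Cluster centers are genes strictly denser than every neighbor.
Outlier prototypes are controlled by `outlier_threshold`:

* default `"mean"` (or a float cutoff): every gene with density below the
  global mean density is an outlier prototype, and local density minima
  above the cutoff stay ordinary;
* `None`: the strict local rule — a gene strictly less dense than every
  neighbor is an outlier.

The default follows the FLAME-style local-approximation procedure this
method builds on, where the outlier definition carries a density
threshold. The threshold matters: under the strict rule alone the
least-dense member of a tight module is, by construction, less dense than
all its (intra-module) neighbors and becomes an absorbing outlier
prototype *inside* the module; because all modules share one outlier slot
while each center owns its own, roughly half of every module's membership
mass drains into the outlier slot. Conversely, genuinely unclustered
low-density genes rarely satisfy "strictly below **all** neighbors" and
supply too few prototypes for noise to be recognised. On data where every
gene belongs to some co-expression structure (no noise floor), the mean
threshold will label the low-density half of the genes as noise
prototypes — set `outlier_threshold=None` or pass an explicit low cutoff
in that regime.

Membership vectors (length M+1, last slot = outlier) are initialised
one-hot for centers/outliers and uniform 1/(M+1) otherwise, then updated
synchronously (Jacobi-style, for determinism and order independence;
the source does not specify a schedule) as the weighted average of
neighbor vectors, centers and outliers held fixed. Convergence: largest
per-entry change < 1e−6 (default) or 500 sweeps, with a warning on
non-convergence. Two residual paths are recorded: the full objective
E = Σ_x‖p_x − Σ w_xy p_y‖² over all genes, and the same sum restricted to
the updated genes. The restricted sum decreases monotonically (it is what
the sweep contracts); the full E can fluctuate transiently because the
fixed prototypes' residuals change as their neighbors move. On instances
small enough to solve directly, the iterate agrees with the exact solution
of `(I − W_oo) P_o = W_of P_f` to < 1e−6.

Hard assignment is the argmax of the converged vector, ties to the lowest
cluster index (the outlier slot, last, loses ties). Singleton/doubleton
modules are kept; `min_module_size` optionally folds smaller modules into
the outlier set (off by default).

The core path contains no randomness: identical inputs and configuration
give byte-identical outputs at any thread count.

## Evaluation metrics

Relevance = mean over observed modules of the best Jaccard index against
any known module; recovery swaps the roles. Precision averages, over a
gene universe G and over each gene's observed co-cluster partners, the
term `min(|M′_gg′|, |M_gg′|)·Φ_gg′ / |M′_gg′|`, where M′_gg′ / M_gg′ are
the observed / known modules containing both genes and Φ is the mean
best-Jaccard of the former against the latter; recall swaps observed and
known. The printed formula leaves empty-set cases open; the conventions
here (pinned by a brute-force oracle in the test suite) are: no known
module containing both genes ⇒ Φ = 0; no observed module containing both
⇒ the pair contributes 0; a gene in no observed module has only its
self-pair, contributing 0.

Normalisation divides each raw score by its mean over B permuted versions
of the known modules — gene labels permuted over the union of known-module
genes, module count and sizes preserved (the permutation scheme is
otherwise unspecified in the source; label permutation is the
least-structured choice). B = 500 by default; the tests use smaller B with
Monte-Carlo-aware tolerances. The overall score is the harmonic mean of
the four normalised scores, 0 if any is 0. Observed modules drawn from the
permutation null normalise to 1.0 within Monte-Carlo error (checked at
B = 200).

Cross-validation splits the **known modules** (not genes) into k folds so
held-out modules are fully unseen; a user-supplied runner maps training
modules to detected modules and is scored against the held-out fold.

## Module-based survival analysis

Module genes are z-scored across patients (population, n, denominator)
and sign-aligned: the gene with the largest summed |correlation| is the
reference (+1; ties by lexicographic id) and every other gene takes the
sign of its correlation with the reference. Zero-variance genes are
dropped; a module reduced below 2 usable genes is an error. The
per-patient statistic is σᵢ, the population standard deviation of the
aligned z-scores within patient i (low σ = tight co-expression). Patients
with σ strictly above the median form one group, ties and below the
other, and the two survival curves are compared with the standard
log-rank χ² (via lifelines; it matches a hand tabulation of
observed-minus-expected events exactly). A constant statistic gives a
degenerate flagged result with p = 1. The same split is run with the
per-patient mean of aligned z-scores and with the orientation reference
gene's raw expression as the single-gene baseline. The screen reports raw
p per module and mode, Benjamini–Hochberg FDR within mode, group sizes,
and Kaplan–Meier coordinates. The recipe generalises the three-gene
description in the source to arbitrary module size by the same steps.

The log-rank χ² reference is mildly liberal in cohorts of ~100–200
patients (empirical null rejection ≈ 0.055 at α = 0.05 over thousands of
simulated modules); this is a property of the asymptotic approximation,
not of the implementation, which matches the textbook statistic exactly.

## Synthetic-data generator

The generator emulates the study design the method targets: two (default)
omics layers over 50 samples each, with 50% shared samples and 60% shared
genes; 5 planted modules of 20 genes on a 200-gene background;
within-module correlation ρ = 0.8; one TF per module covering 50% of its
genes plus ~10% decoy edges; survival times exponential with log-hazard
proportional to the standardised per-patient co-expression σ of one
designated causal module (effect 1.5 per SD, baseline hazard 0.1,
~30% independent exponential censoring).

Module gene g has profile `s_g·(a_g·f_m + sqrt(1−a_g²)·ε)` with a fresh
noise draw per layer, factor f_m per sample, sign s_g = −1 for 25% of
members (so orientation is exercised) and loading
`a_g ~ U(sqrt(ρ) ± 0.15)` clipped below 1. The heterogeneous loadings give
modules hub structure — some genes track the factor tightly, others
loosely — as real co-expression modules have; the mean pairwise |r| stays
at E[a]² ≈ ρ. Background genes are independent N(0,1) per layer. An
optional MCAR missingness injector exercises the filter/impute path.

What the generator does **not** emulate: real expression distributions,
batch effects, transcript–protein discordance beyond independent noise,
structured (informative) censoring, or overlapping/nested modules.
Passing the planted-recovery benchmark therefore shows the pipeline
separates block-correlated structure from an uncorrelated background at
realistic sample sizes — not that it reproduces any particular biological
dataset.

## Preprocessing

Genes with **strictly more** than 20% missing values are removed (a gene
at exactly the threshold is kept). Remaining gaps are filled by KNN
imputation over the gene axis: distances are Euclidean over co-observed
samples scaled by sqrt(n_total/n_observed), donors are the k (default 10,
matching the clustering k) nearest genes carrying a value in the gapped
sample, combined by 1/distance weights. Duplicate gene rows are collapsed
by their mean before filtering. Missing-value spellings accepted in TSV:
empty cell, NA, NaN, null (any case).

## Problem sizes used in validation

The automated checks run the full pipeline on the default synthetic
scenario (300 genes × 2 layers × 50 samples, 10 generator seeds), solve
the membership system directly on graphs of ≤ 30 objects, evaluate the
metric oracles exhaustively over 6-gene module-set pairs, calibrate the
permutation normalisation at B = 200 on a 40-gene collection, and
simulate 400 null modules of 100 patients for the type-I-error check.
These sizes were chosen so every oracle remains exactly computable while
the pipeline still operates in its intended regime (hundreds of genes,
tens of samples per layer).
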