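# Methods

## Problem and model

`drivergcn` prioritizes candidate cancer driver genes for individual tumor
samples. Driver genes — those whose somatic alterations confer a selective
growth advantage — are usually called at the cohort level; here each patient
gets their own ranked list, so rarely mutated drivers that population
methods miss can surface in the patients they actually affect.

The method has two stages.

**1. Per-patient network construction.** For each tumor sample, the genes of
interest are the sample's mutated genes (binary non-silent mutation calls)
united with the cohort's differentially expressed genes (DEGs). The
protein-interaction subgraph induced on this subset (STRING-style edge list,
combined score ≥ 700 by default) is the sample's subnetwork; isolated genes
are kept as degree-0 nodes. The cohort graph is the disjoint union over
samples: every node is a (sample, gene) pair, its adjacency matrix A is
block-diagonal, and no edge crosses samples. Nodes are labeled positive when
the gene belongs to a curated driver catalogue, negative otherwise; labeled
nodes are split 75/25 into train/test, stratified by label.

DEGs are called tumor-vs-control on log2 expression by intersecting two
tests — a Welch two-sample t-test and a one-way ANOVA F-test — each
Benjamini–Hochberg adjusted; a gene is a DEG when both adjusted p < 0.05 and
|log2 fold-change| > 2 (the fold-change is a difference of means because the
input is already log2). Intersecting two testing routes reduces
single-method bias; an externally supplied DEG list can bypass both.

**2. Node classification.** Each node carries a feature vector of three
blocks, min–max scaled to [0, 1] per column:

- *molecular* (4): the node's own sample row of mutation, expression,
  methylation (beta value) and GISTIC2 copy-number category;
- *system-level* (18): global gene properties (gene length, protein-domain
  count, gene age, essentiality, …) supplied as a table; genes absent from
  the table are zero-filled so the node set never shrinks;
- *structural* (d = 20 by default): node2vec embedding of the full
  disjoint-union graph — second-order biased random walks (return p, in-out
  q) fed to skip-gram with negative sampling. Walks cannot leave a connected
  component, so each sample's subgraph is embedded from its own context;
  degree-0 nodes get the zero vector.

The classifier is a two-layer graph convolutional network over the
symmetric-normalized adjacency with self-loops, Â = D̃^{-1/2}(A + I)D̃^{-1/2},
with a conditional-random-field (CRF) block between the layers. The first
convolution produces embeddings Q = ReLU(Â X W¹); the CRF block pulls each
embedding toward an attention-weighted average of its neighbors while
anchoring it to Q,

    H_i ← (α Q_i + β Σ_{j∈M_i} g_ij H_j) / (α + β Σ_{j∈M_i} g_ij),

iterated T times from H⁰ = Q. The pairwise weights g_ij are a per-
neighborhood softmax of GAT-style scores LeakyReLU(a·[W_t H_i ‖ W_t H_j])
(slope 0.2). The same α, β weight the CRF energy

    l_CRF = Σ_i ( α‖H_i − Q_i‖² + β Σ_{j∈M_i} g_ij ‖H_i − H_j‖² ),

which joins the supervised loss. The second convolution maps H to a logit
and a sigmoid gives the node score h ∈ (0, 1). The supervised term is
class-weighted binary cross-entropy, l_θ = −mean(p·y·log h + (1−y)·log(1−h))
over training nodes, with p ≥ 1 up-weighting the minority positive class.
The total loss l_CRF + l_θ is minimized with Adam; l_θ is averaged over
training nodes only while l_CRF covers all nodes (it is unsupervised
smoothing in a transductive setting).

Scores become per-sample rankings (descending score, ties broken
lexicographically) and a population-level ranking (per-gene max over that
gene's nodes by default; mean available). Reports include accuracy / ROC
AUC / area under the precision–recall curve on held-out nodes, top-k
precision–recall–F1 against a reference catalogue, per-sample top-k
reference hits, and rare-driver flags: genes ranked in a sample's top-k,
mutated in at least one sample, with cohort mutation frequency < 2%.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| `string_score_threshold` | 700 | STRING "high confidence" edge cutoff |
| `deg_alpha`, `deg_lfc` | 0.05, 2.0 | DEG gates (BH-adjusted p, abs log2 FC) |
| `hidden_dim` | 64 | width of the GCN embedding the CRF refines |
| `crf_alpha`, `crf_beta` | 1, 1 | anchor vs smooth balance; β=0 disables the CRF |
| `crf_iterations` | 2 | unrolled update steps T |
| `positive_weight` | 1 | p in the weighted cross-entropy (3 and 2 suit heavily imbalanced cohorts of the two reference sizes) |
| `learning_rate`, `weight_decay`, `dropout`, `epochs` | 0.001, 0.005, 0.1, 3000 | Adam recipe; weight decay is a coupled L2 penalty |
| `node2vec.dim` | 20 | structural block width (10/20/30 all reasonable) |
| `node2vec` walks | length 80, 10 per node, window 5, p=q=1, 5 negatives, 5 epochs | reference random-walk settings |
| `test_fraction` | 0.25 | held-out fraction of labeled nodes |

## Numerical choices

- **CRF energy scale.** The training objective uses the CRF energy
  *averaged over nodes* so that it shares the per-node scale of the (mean)
  cross-entropy. With the raw summed energy the smoothing term is two
  orders of magnitude larger than l_θ at desk scale and Adam simply
  collapses the embeddings to zero; averaging restores the intended balance
  while α and β keep their roles. The standalone `crf_loss()` helper
  reports the summed energy.
- **Attention stability.** Softmax scores are shifted by the per-
  neighborhood maximum before exponentiation; probabilities entering logs
  are clamped to [1e-7, 1 − 1e-7].
- **Degenerate inputs.** Isolated nodes keep Â_ii = 1 (their own signal
  survives convolution) and keep H_i = Q_i in the CRF block; constant
  feature columns min–max scale to 0; zero-variance genes in both DEG
  groups get p = 1 with a warning; a training mask with a single class is
  rejected.
- **Tie-breaks.** Rankings order by descending score then gene symbol, so
  outputs are byte-reproducible.
- **Skip-gram optimization.** Pairs are processed in batches that scale
  with the vocabulary (4 × n_nodes, minimum 256) and the accumulated
  gradient of each embedding row is averaged within a batch; summing
  instead makes the effective step proportional to a row's multiplicity in
  the batch and diverges on small graphs. Learning rate decays linearly
  from 0.025 to 1e-4.
- **Determinism.** All randomness (simulation, walks, skip-gram, parameter
  initialization, dropout, splits) flows from explicit seeds through
  numpy `default_rng`; identical seed and configuration reproduce loss
  traces, scores, rankings and report files byte-for-byte.
- **Gradients.** The model runs on a small reverse-mode autodiff engine
  over float64 numpy arrays; analytic gradients agree with central
  differences to ~1e-8 floored relative error on small instances.

## Synthetic cohorts

`drivergcn.synthetic` generates complete cohorts in exactly the shapes the
loaders read, with planted, tunable driver signal. Defaults: 20 tumor + 20
control samples × 300 genes, 30 drivers. Drivers mutate at 40% (background
2%), gain +3 log2 expression and +0.2 methylation in the samples where they
are mutated, carry copy-number events at 30% (background 5%), have their 18
gene-property columns offset by +1 SD, and attach with 3× weight in the
preferential-attachment interaction graph (3 edges per node, scores uniform
in [700, 999]). Expression baselines are N(6, 1) per gene with N(0, 0.5)
sample noise; methylation baselines are Beta(2, 2) with 0.05 noise, clipped
to [0, 1]. Every channel can be nulled independently;
`SimulationConfig.null()` equalizes mutation rates at 0.1 and removes all
shifts, offsets and hub bias.

What the simulator does *not* emulate: real mutational processes (no
gene-length or replication-timing covariates), correlated methylation
blocks, GISTIC2 segment structure, STRING's actual topology, or alias/
coverage problems of real gene identifiers. Passing the planted-signal
tests shows the pipeline can recover a known multi-omics signal through the
whole network-feature-model path; it does not certify performance on real
cohorts.

A caveat worth knowing: gene labels are gene-level while the train/test
split is node-level, so nodes of a gene mutated in several samples can land
on both sides of the split with identical per-gene features. Any
sufficiently flexible model therefore scores somewhat above chance on a
*null* cohort by memorizing realized gene signatures — on null features a
random forest reaches held-out AUC > 0.9 while this model, at the default
recipe, stays near 0.5–0.7. Gene-disjoint splitting would remove the effect
but changes the transductive protocol; we keep the standard protocol and
note the effect.

## Problem sizes used in tests and the acceptance script

End-to-end checks run the default 20 × 300 cohort with 500 training epochs
and a reduced walk corpus (walk length 40, 5 walks per node, 3 skip-gram
epochs) — enough for the structural block to separate components while
keeping a full pipeline run under ~10 s. The CLI smoke test uses the full
default configuration (3000 epochs, reference walk settings).
`scripts/acceptance.py` averages 3 replicate cohorts per condition.

## Known limitations

- DEG calling uses Welch t + ANOVA F intersection, not an empirical-Bayes
  moderated fit; with very few controls its power is limited.
- DEGs are cohort-level; per-sample DEG calling is a natural extension.
- No gene-alias resolution: symbol matching is uppercase-exact.
- No built-in coding/non-coding filter: `load_cohort(keep_genes=...)`
  accepts an explicit keep-list instead of guessing a biotype rule.
- The grid search (`grid_search_cv`) retrains per fold and combination; it
  is practical for small grids only.
- Population-level aggregation (max) favors genes that drive any single
  patient strongly; use mean for consensus behavior.
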