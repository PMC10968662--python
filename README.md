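# drivergcn

Personalized cancer driver gene prioritization: per-patient sample–gene
interaction networks from multi-omics data, scored with a graph
convolutional network (GCN) refined by a conditional-random-field (CRF)
layer.

Most driver-gene callers work at the population level and miss drivers that
are rare in a cohort but decisive for the patients who carry them. This
package builds one interaction subnetwork per patient — the
protein-interaction graph induced on that patient's mutated genes plus the
cohort's differentially expressed genes — takes the disjoint union across
patients (every node is a *(sample, gene)* pair), and classifies nodes as
driver/non-driver, yielding a ranked candidate list per patient.

## The model

Each node carries molecular features (mutation bit, log2 expression,
methylation beta, copy-number category), 18 system-level gene properties,
and a node2vec embedding of the graph, concatenated and min–max scaled.
With Â = D̃<sup>−1/2</sup>(A + I)D̃<sup>−1/2</sup> the scores are

    Q = ReLU(Â X W¹)                                  first convolution
    H_i ← (α Q_i + β Σ_j g_ij H_j) / (α + β Σ_j g_ij)  CRF refinement, T steps
    h   = σ(Â H W²)                                   output scores in (0,1)

where g<sub>ij</sub> is an attention softmax over node i's neighborhood.
Training minimizes l<sub>CRF</sub> + l<sub>θ</sub>: the CRF energy
α‖H−Q‖² + β Σ g<sub>ij</sub>‖H<sub>i</sub>−H<sub>j</sub>‖² (keep similar
neighbors similar, stay anchored to the convolution output) plus
class-weighted binary cross-entropy
−mean(p·y·log h + (1−y)·log(1−h)) with p ≥ 1 compensating the scarcity of
known drivers. See `docs/methods.md` for assumptions, defaults and
limitations.

A complete synthetic-cohort generator (`drivergcn.synthetic`) emulates all
required input shapes — omics matrices, STRING-style edge list, gene
property table, driver list — with planted, tunable driver signal, so the
whole pipeline runs and is tested without any external download.

## Worked example

```python
from drivergcn import RunConfig, SimulationConfig, run_pipeline, simulate
from drivergcn.config import Node2vecConfig

bundle = simulate(SimulationConfig(seed=0))   # 20 samples x 300 genes, 30 drivers
config = RunConfig(epochs=500, seed=0,
                   node2vec=Node2vecConfig(dim=20, walk_length=40,
                                           walks_per_node=5, epochs=3))
result = run_pipeline(bundle.cohort, bundle.ppi, bundle.system_table,
                      bundle.labels, config)
print(result.test_metrics)
print(result.prediction.sample_rankings["S000"][:3])
```

prints

```
{'acc': 0.9285714285714286, 'auc': 0.9826388888888888, 'aupr': 0.992972032591302}
[('G0020', 0.9732...), ('G0182', 0.8188...), ('G0173', 0.7937...)]
```

i.e. on held-out nodes the model separates planted driver nodes from
background almost perfectly (ROC AUC 0.983, AUPR 0.993), and sample `S000`'s
three top-ranked genes are all planted drivers mutated in that sample. The same flow
works from the shell:

```sh
drivergcn simulate --out data --seed 0
drivergcn build-network --data data --out graph
drivergcn featurize --data data --graph graph --out features
drivergcn train --graph graph --features features --out model.npz
drivergcn predict --model model.npz --graph graph --features features --out scores.tsv
drivergcn evaluate --data data --graph graph --scores scores.tsv --out reports
```

`reports/` then holds per-sample rankings, the population-level ranking,
accuracy/AUC/AUPR tables, per-sample top-k reference hits, and the
rare-driver table (genes ranked top-k in some sample yet mutated in < 2% of
the cohort).

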