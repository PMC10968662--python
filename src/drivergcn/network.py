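"""Patient-specific network construction.

For each tumor sample, the genes of interest are that sample's mutated
genes plus the cohort-level differentially expressed genes (DEGs); the
protein-interaction subgraph induced on this gene subset is the sample's
subnetwork.  The full sample-gene interaction network is the disjoint
union of these subnetworks: every node is a (sample, gene) pair, and no
edge crosses samples.  Nodes are labeled positive when the gene belongs
to the known driver catalogue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

from .io import CohortData, LabelCatalogue, PPITable

logger = logging.getLogger("drivergcn")


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


@dataclass
class DEGResult:
    """Cohort-level differential-expression call, tumor vs control.

    Two tests are run per gene — a Welch two-sample t-test and a one-way
    ANOVA F-test — each Benjamini-Hochberg adjusted independently; a gene
    is a DEG only when both adjusted p-values clear `deg_alpha` AND the
    log2 fold-change exceeds `deg_lfc` in magnitude (expression input is
    already log2, so the fold-change is a difference of group means).
    """

    table: pd.DataFrame  # index gene; log2fc, pvalue_welch, pvalue_anova,
    # adj_pvalue_welch, adj_pvalue_anova, is_deg

    @property
    def deg_set(self) -> set[str]:
        return set(self.table.index[self.table["is_deg"]])


def call_degs(
    tumor_expression: pd.DataFrame,
    control_expression: pd.DataFrame,
    deg_alpha: float = 0.05,
    deg_lfc: float = 2.0,
) -> DEGResult:
    genes = [g for g in tumor_expression.columns if g in set(control_expression.columns)]
    if len(tumor_expression) < 2 or len(control_expression) < 2:
        raise ValueError("insufficient replicates: need >= 2 samples per group")
    t = tumor_expression[genes].to_numpy(float)
    c = control_expression[genes].to_numpy(float)

    log2fc = t.mean(axis=0) - c.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p_welch = stats.ttest_ind(t, c, axis=0, equal_var=False)
        _, p_anova = stats.f_oneway(t, c, axis=0)
    zero_var = (t.var(axis=0) == 0) & (c.var(axis=0) == 0)
    if zero_var.any():
        logger.warning("%d genes have zero variance in both groups; p set to 1",
                       int(zero_var.sum()))
    p_welch = np.where(np.isnan(p_welch) | zero_var, 1.0, p_welch)
    p_anova = np.where(np.isnan(p_anova) | zero_var, 1.0, p_anova)

    adj_welch = multipletests(p_welch, method="fdr_bh")[1]
    adj_anova = multipletests(p_anova, method="fdr_bh")[1]
    is_deg = (
        (adj_welch < deg_alpha)
        & (adj_anova < deg_alpha)
        & (np.abs(log2fc) > deg_lfc)
    )
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue_welch": p_welch,
            "pvalue_anova": p_anova,
            "adj_pvalue_welch": adj_welch,
            "adj_pvalue_anova": adj_anova,
            "is_deg": is_deg,
        },
        index=pd.Index(genes, name="gene"),
    )
    logger.info("DEG calling: %d / %d genes differential", int(is_deg.sum()), len(genes))
    return DEGResult(table=table)


# ---------------------------------------------------------------------------
# per-sample subnetworks and their disjoint union
# ---------------------------------------------------------------------------


@dataclass
class SampleSubnet:
    """One patient's induced interaction subnetwork."""

    sample_id: str
    genes: list[str]  # sorted gene subset: mutated(sample) | DEG(cohort)
    edges: list[tuple[str, str]]  # induced PPI edges within `genes`


def build_sample_subnet(
    sample_id: str,
    mutation_row: pd.Series,
    deg_set: set[str],
    ppi: PPITable,
) -> SampleSubnet:
    universe = set(mutation_row.index)
    mutated = {g for g in mutation_row.index[mutation_row.astype(int) == 1]}
    subset = mutated | (set(deg_set) & universe)
    if not subset:
        logger.warning("sample %s has no mutated or differential genes", sample_id)
        return SampleSubnet(sample_id=sample_id, genes=[], edges=[])
    edges = [
        (a, b) if a < b else (b, a)
        for a, b in zip(ppi.edges["gene_a"], ppi.edges["gene_b"])
        if a in subset and b in subset
    ]
    return SampleSubnet(sample_id=sample_id, genes=sorted(subset), edges=sorted(set(edges)))


@dataclass
class InteractionGraph:
    """Disjoint union of per-sample subnetworks.

    Node i is the pair (node_samples[i], node_genes[i]); `adjacency` is
    symmetric binary with zero diagonal and, by construction, block
    diagonal over samples.
    """

    node_samples: np.ndarray  # (n,) str
    node_genes: np.ndarray  # (n,) str
    adjacency: sp.csr_matrix  # (n, n) binary
    labels: Optional[np.ndarray] = None  # (n,) in {0,1}
    train_mask: Optional[np.ndarray] = None  # (n,) bool
    test_mask: Optional[np.ndarray] = None  # (n,) bool

    @property
    def n_nodes(self) -> int:
        return len(self.node_genes)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def node_index(self) -> dict[tuple[str, str], int]:
        return {
            (s, g): i
            for i, (s, g) in enumerate(zip(self.node_samples, self.node_genes))
        }


def assemble_cohort_graph(subnets: Sequence[SampleSubnet]) -> InteractionGraph:
    """Concatenate per-sample node lists and take the block-diagonal
    union of their adjacency matrices."""
    subnets = [s for s in subnets if s.genes]
    if not subnets:
        raise ValueError("no non-empty sample subnetworks")
    node_samples: list[str] = []
    node_genes: list[str] = []
    rows: list[int] = []
    cols: list[int] = []
    offset = 0
    for net in subnets:
        idx = {g: offset + k for k, g in enumerate(net.genes)}
        node_samples.extend([net.sample_id] * len(net.genes))
        node_genes.extend(net.genes)
        for a, b in net.edges:
            ia, ib = idx[a], idx[b]
            rows.extend((ia, ib))
            cols.extend((ib, ia))
        offset += len(net.genes)
    n = offset
    adjacency = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    adjacency.data[:] = 1.0  # collapse any duplicate entries
    graph = InteractionGraph(
        node_samples=np.array(node_samples, dtype=object),
        node_genes=np.array(node_genes, dtype=object),
        adjacency=adjacency,
    )
    logger.info(
        "assembled graph: %d nodes, %d edges across %d samples",
        graph.n_nodes, graph.n_edges, len(subnets),
    )
    return graph


def build_cohort_graph(
    cohort: CohortData,
    ppi: PPITable,
    deg_set: set[str] | None = None,
) -> InteractionGraph:
    """Convenience: per-sample subnets for every cohort sample, unioned."""
    deg_set = deg_set or set()
    subnets = [
        build_sample_subnet(s, cohort.mutation.loc[s], deg_set, ppi)
        for s in cohort.sample_ids
    ]
    return assemble_cohort_graph(subnets)


def assign_labels(graph: InteractionGraph, catalogue: LabelCatalogue) -> InteractionGraph:
    """Label node positive iff its gene is in the driver catalogue."""
    positives = catalogue.positive_genes
    labels = np.array([1 if g in positives else 0 for g in graph.node_genes], dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0:
        raise ValueError("zero positive nodes: no catalogue gene occurs in the graph")
    if n_neg == 0:
        raise ValueError("zero negative nodes: every graph gene is in the catalogue")
    logger.info("labels assigned: %d positive, %d negative nodes", n_pos, n_neg)
    graph.labels = labels
    return graph


def split_nodes(
    graph: InteractionGraph, test_fraction: float = 0.25, seed: int = 0
) -> InteractionGraph:
    """Stratified train/test split over all labeled nodes."""
    if graph.labels is None:
        raise ValueError("labels must be assigned before splitting")
    n = graph.n_nodes
    if test_fraction == 0:
        logger.warning("test_fraction is 0: all nodes assigned to training")
        graph.train_mask = np.ones(n, dtype=bool)
        graph.test_mask = np.zeros(n, dtype=bool)
        return graph
    counts = np.bincount(graph.labels, minlength=2)
    if counts.min() < 2:
        raise ValueError(f"a label stratum has < 2 nodes: {counts.tolist()}")
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=graph.labels,
        random_state=seed,
    )
    train_mask = np.zeros(n, dtype=bool)
    test_mask = np.zeros(n, dtype=bool)
    train_mask[train_idx] = True
    test_mask[test_idx] = True
    graph.train_mask = train_mask
    graph.test_mask = test_mask
    return graph


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def export_graph(graph: InteractionGraph, directory: str | Path) -> None:
    """Write node table + 0-based edge list as TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        {
            "sample_id": graph.node_samples,
            "gene": graph.node_genes,
            "label": graph.labels if graph.labels is not None else -1,
            "mask": _mask_column(graph),
        }
    )
    nodes.to_csv(directory / "nodes.tsv", sep="\t", index_label="node_index")
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    edges = pd.DataFrame({"node_index_a": coo.row, "node_index_b": coo.col})
    edges.to_csv(directory / "edges.tsv", sep="\t", index=False)


def _mask_column(graph: InteractionGraph) -> list[str]:
    if graph.train_mask is None:
        return ["unset"] * graph.n_nodes
    return [
        "train" if tr else ("test" if te else "unset")
        for tr, te in zip(graph.train_mask, graph.test_mask)
    ]


def import_graph(directory: str | Path) -> InteractionGraph:
    directory = Path(directory)
    nodes = pd.read_csv(directory / "nodes.tsv", sep="\t", index_col=0)
    edges = pd.read_csv(directory / "edges.tsv", sep="\t")
    n = len(nodes)
    rows = np.concatenate([edges["node_index_a"], edges["node_index_b"]])
    cols = np.concatenate([edges["node_index_b"], edges["node_index_a"]])
    adjacency = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    labels = nodes["label"].to_numpy(int)
    mask = nodes["mask"].astype(str)
    graph = InteractionGraph(
        node_samples=nodes["sample_id"].to_numpy(object),
        node_genes=nodes["gene"].to_numpy(object),
        adjacency=adjacency,
        labels=None if (labels < 0).all() else labels,
    )
    if (mask != "unset").any():
        graph.train_mask = (mask == "train").to_numpy()
        graph.test_mask = (mask == "test").to_numpy()
    return graph
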