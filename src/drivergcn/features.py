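"""Node feature assembly.

Each node (sample, gene) of the interaction graph gets three feature
blocks: a molecular block of 4 scalars read from that sample's omics rows
(mutation, expression, methylation, copy number), an 18-column block of
global gene properties, and a structural block from the random-walk
embedding of the graph.  Blocks are concatenated and min-max scaled to
[0, 1] per column (constant columns map to 0); the scaling bounds are
recorded so inference can reuse them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Node2vecConfig
from .embedding import node2vec_embed
from .io import CohortData, SystemFeatureTable
from .network import InteractionGraph

logger = logging.getLogger("drivergcn")

MOLECULAR_COLUMNS = ("mutation", "expression", "methylation", "cnv")


@dataclass
class NodeFeatureMatrix:
    """Normalized per-node features with block layout and scaling bounds."""

    X: np.ndarray  # (n_nodes, 4 + 18 + d), entries in [0, 1]
    block_spec: dict[str, tuple[int, int]]  # block -> [start, stop) columns
    bounds: np.ndarray  # (2, n_columns): per-column (min, max) pre-scaling

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def molecular_features(graph: InteractionGraph, cohort: CohortData) -> np.ndarray:
    """Per-node (mutation, expression, methylation, cnv) from the node's
    own sample row."""
    gene_pos = {g: i for i, g in enumerate(cohort.gene_ids)}
    sample_pos = {s: i for i, s in enumerate(cohort.sample_ids)}
    missing = [
        (s, g)
        for s, g in zip(graph.node_samples, graph.node_genes)
        if g not in gene_pos or s not in sample_pos
    ]
    if missing:
        raise ValueError(f"nodes absent from cohort matrices: {missing[:5]}")
    rows = np.array([sample_pos[s] for s in graph.node_samples])
    cols = np.array([gene_pos[g] for g in graph.node_genes])
    mats = [
        cohort.mutation.to_numpy(float),
        cohort.expression.to_numpy(float),
        cohort.methylation.to_numpy(float),
        cohort.cnv.to_numpy(float),
    ]
    return np.column_stack([m[rows, cols] for m in mats])


def system_features(graph: InteractionGraph, table: SystemFeatureTable) -> np.ndarray:
    """Per-node 18-vector of its gene's global properties; genes missing
    from the table get an all-zero row."""
    feats = table.features
    out = np.zeros((graph.n_nodes, SystemFeatureTable.N_FEATURES))
    known = set(table.gene_ids)
    present = np.array([g in known for g in graph.node_genes])
    if present.any():
        out[present] = feats.loc[
            np.asarray(graph.node_genes)[present].tolist()
        ].to_numpy(float)
    n_missing = int((~present).sum())
    if n_missing:
        logger.info(
            "%d nodes have genes absent from the system-feature table (zero-filled)",
            n_missing,
        )
    return out


def structural_features(graph: InteractionGraph, config: Node2vecConfig) -> np.ndarray:
    """Random-walk embedding of the full disjoint-union graph."""
    return node2vec_embed(graph.adjacency, config)


def concat_normalize(blocks: dict[str, np.ndarray]) -> NodeFeatureMatrix:
    """Concatenate named blocks column-wise and min-max scale each column."""
    mats = list(blocks.values())
    n_rows = {m.shape[0] for m in mats}
    if len(n_rows) != 1:
        raise ValueError(f"blocks have mismatched row counts: {sorted(n_rows)}")
    spec: dict[str, tuple[int, int]] = {}
    start = 0
    for name, m in blocks.items():
        spec[name] = (start, start + m.shape[1])
        start += m.shape[1]
    raw = np.hstack(mats).astype(np.float64)
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    X = apply_bounds(raw, np.vstack([lo, hi]))
    return NodeFeatureMatrix(X=X, block_spec=spec, bounds=np.vstack([lo, hi]))


def apply_bounds(raw: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Min-max scale `raw` with recorded bounds; constant columns -> 0."""
    lo, hi = bounds
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    X = (raw - lo) / safe
    X[:, span == 0] = 0.0
    return X


def assemble_features(
    graph: InteractionGraph,
    cohort: CohortData,
    table: SystemFeatureTable,
    node2vec: Node2vecConfig | None = None,
) -> NodeFeatureMatrix:
    """Molecular + system + (optional) structural blocks, normalized."""
    blocks = {
        "molecular": molecular_features(graph, cohort),
        "system": system_features(graph, table),
    }
    if node2vec is not None and node2vec.dim > 0:
        blocks["structural"] = structural_features(graph, node2vec)
    return concat_normalize(blocks)


def export_features(fm: NodeFeatureMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(fm.X).to_csv(
        directory / "features.tsv", sep="\t", index_label="node_index"
    )
    sidecar = pd.DataFrame(
        {
            "column": range(fm.n_columns),
            "block": [
                next(n for n, (a, b) in fm.block_spec.items() if a <= j < b)
                for j in range(fm.n_columns)
            ],
            "min": fm.bounds[0],
            "max": fm.bounds[1],
        }
    )
    sidecar.to_csv(directory / "feature_bounds.tsv", sep="\t", index=False)


def import_features(directory: str | Path) -> NodeFeatureMatrix:
    directory = Path(directory)
    X = pd.read_csv(directory / "features.tsv", sep="\t", index_col=0).to_numpy(float)
    sidecar = pd.read_csv(directory / "feature_bounds.tsv", sep="\t")
    spec: dict[str, tuple[int, int]] = {}
    for name, grp in sidecar.groupby("block", sort=False):
        spec[name] = (int(grp["column"].min()), int(grp["column"].max()) + 1)
    bounds = np.vstack([sidecar["min"].to_numpy(), sidecar["max"].to_numpy()])
    return NodeFeatureMatrix(X=X, block_spec=spec, bounds=bounds)
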