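"""End-to-end orchestration: cohort -> graph -> features -> model -> reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import RunConfig
from .evaluation import (
    PredictionResult,
    compute_metrics,
    flag_rare_drivers,
    per_sample_hits,
    write_reports,
)
from .features import NodeFeatureMatrix, assemble_features
from .io import CohortData, LabelCatalogue, PPITable, SystemFeatureTable
from .model import GCNCRFClassifier
from .network import (
    InteractionGraph,
    assign_labels,
    build_cohort_graph,
    call_degs,
    split_nodes,
)

logger = logging.getLogger("drivergcn")


@dataclass
class PipelineResult:
    graph: InteractionGraph
    features: NodeFeatureMatrix
    model: GCNCRFClassifier
    prediction: PredictionResult
    train_metrics: dict[str, float]
    test_metrics: dict[str, float]


def build_graph(
    cohort: CohortData,
    ppi: PPITable,
    catalogue: LabelCatalogue,
    config: RunConfig,
) -> InteractionGraph:
    """DEG calling (when controls exist), per-sample subnets, union,
    labels and stratified split."""
    deg_set: set[str] = set()
    if cohort.control_expression is not None:
        deg_set = call_degs(
            cohort.expression,
            cohort.control_expression,
            deg_alpha=config.deg_alpha,
            deg_lfc=config.deg_lfc,
        ).deg_set
    graph = build_cohort_graph(cohort, ppi, deg_set)
    graph = assign_labels(graph, catalogue)
    return split_nodes(graph, test_fraction=config.test_fraction, seed=config.seed)


def run_pipeline(
    cohort: CohortData,
    ppi: PPITable,
    system_table: SystemFeatureTable,
    catalogue: LabelCatalogue,
    config: RunConfig | None = None,
    use_node2vec: bool = True,
    reference: Optional[set[str]] = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full method and (optionally) write the report bundle.

    `reference` is the catalogue used for top-k benchmarking; it defaults
    to the positive label catalogue.
    """
    config = config or RunConfig()
    config.validate()
    graph = build_graph(cohort, ppi, catalogue, config)
    n2v = config.node2vec if use_node2vec else None
    if n2v is not None:
        n2v.seed = config.seed
    fm = assemble_features(graph, cohort, system_table, node2vec=n2v)

    model = GCNCRFClassifier(
        hidden_dim=config.hidden_dim,
        alpha=config.crf_alpha,
        beta=config.crf_beta,
        crf_iterations=config.crf_iterations,
        positive_weight=config.positive_weight,
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
        dropout=config.dropout,
        epochs=config.epochs,
        random_state=config.seed,
    )
    model.fit(fm.X, graph.labels, adjacency=graph.adjacency, train_mask=graph.train_mask)
    scores = model.predict_proba(fm.X)[:, 1]
    prediction = PredictionResult(graph=graph, scores=scores)

    train_metrics = compute_metrics(scores, graph.labels, graph.train_mask)
    test_metrics = compute_metrics(scores, graph.labels, graph.test_mask)
    logger.info("train metrics: %s", train_metrics)
    logger.info("test metrics: %s", test_metrics)

    if outdir is not None:
        reference = reference or set(catalogue.positive_genes)
        hits = per_sample_hits(prediction, reference)
        rare = flag_rare_drivers(prediction, cohort.mutation)
        write_reports(
            outdir,
            prediction,
            metrics={**{f"test_{k}": v for k, v in test_metrics.items()},
                     **{f"train_{k}": v for k, v in train_metrics.items()}},
            hits=hits,
            rare=rare,
            extra_summary={"config": config.to_dict()},
        )
    return PipelineResult(
        graph=graph,
        features=fm,
        model=model,
        prediction=prediction,
        train_metrics=train_metrics,
        test_metrics=test_metrics,
    )
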