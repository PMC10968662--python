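"""Shared fixtures: tiny hand-built cohorts and cached end-to-end runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from drivergcn import (
    CohortData,
    LabelCatalogue,
    PPITable,
    RunConfig,
    SimulationConfig,
    run_pipeline,
    simulate,
)
from drivergcn.config import Node2vecConfig


def light_node2vec(**kw) -> Node2vecConfig:
    """Walk budget used by end-to-end tests (smaller corpus, same model)."""
    defaults = dict(dim=20, walk_length=40, walks_per_node=5, window=5, epochs=3)
    defaults.update(kw)
    return Node2vecConfig(**defaults)


def pipeline_config(seed: int, **kw) -> RunConfig:
    defaults = dict(epochs=500, seed=seed, node2vec=light_node2vec())
    defaults.update(kw)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def planted_runs():
    """Full model (CRF + structural features) on the default planted-signal
    cohort, seeds 0-4; reused by recovery, ablation and report tests."""
    runs = []
    for seed in range(5):
        bundle = simulate(SimulationConfig(seed=seed))
        res = run_pipeline(
            bundle.cohort, bundle.ppi, bundle.system_table, bundle.labels,
            pipeline_config(seed),
        )
        runs.append((bundle, res))
    return runs


@pytest.fixture(scope="session")
def plain_gcn_runs():
    """Ablation arm: no CRF block, no structural features; same cohorts."""
    runs = []
    for seed in range(5):
        bundle = simulate(SimulationConfig(seed=seed))
        res = run_pipeline(
            bundle.cohort, bundle.ppi, bundle.system_table, bundle.labels,
            pipeline_config(seed, crf_beta=0.0),
            use_node2vec=False,
        )
        runs.append((bundle, res))
    return runs


@pytest.fixture()
def tiny_cohort() -> CohortData:
    """3 samples x 4 genes with controls; all values hand-chosen."""
    samples = ["s1", "s2", "s3"]
    genes = ["G1", "G2", "G3", "G4"]

    def frame(rows):
        return pd.DataFrame(rows, index=samples, columns=genes)

    return CohortData(
        mutation=frame([[1, 0, 0, 1], [0, 1, 0, 0], [1, 1, 0, 0]]).astype(int),
        expression=frame(
            [[7.2, 5.0, 6.0, 8.0], [5.5, 9.0, 6.1, 7.5], [7.0, 8.8, 5.9, 7.7]]
        ),
        methylation=frame(
            [[0.4, 0.5, 0.6, 0.2], [0.3, 0.9, 0.5, 0.1], [0.45, 0.85, 0.55, 0.15]]
        ),
        cnv=frame([[-1, 0, 0, 2], [0, 1, 0, 0], [-1, 1, 0, 0]]).astype(int),
        control_expression=pd.DataFrame(
            [[5.0, 5.0, 6.0, 7.6], [5.2, 5.1, 6.0, 7.4], [4.9, 5.2, 6.1, 7.5]],
            index=["c1", "c2", "c3"],
            columns=genes,
        ),
    )


@pytest.fixture()
def tiny_ppi() -> PPITable:
    edges = pd.DataFrame(
        {
            "gene_a": ["G1", "G2", "G3"],
            "gene_b": ["G2", "G3", "G4"],
            "score": [900.0, 850.0, 800.0],
        }
    )
    return PPITable(edges=edges, score_threshold=700.0)


@pytest.fixture()
def tiny_catalogue() -> LabelCatalogue:
    return LabelCatalogue(positive_genes=frozenset({"G1", "G4"}))


def random_symmetric_adjacency(n: int, p: float, rng) -> sp.csr_matrix:
    upper = np.triu((rng.random((n, n)) < p).astype(float), k=1)
    return sp.csr_matrix(upper + upper.T)
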