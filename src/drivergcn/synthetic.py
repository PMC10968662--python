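"""Synthetic multi-omics cohort generator with planted driver signal.

Emulates the shapes of a TCGA-style cohort joined with a STRING-style
interaction table: binary somatic mutation, log2 expression (tumor and
control), methylation beta values, GISTIC2-style copy-number categories,
an 18-column gene-property table and a driver-gene label list.  A chosen
subset of genes is planted as drivers: they mutate more often, shift
expression/methylation/copy number in the samples where they are mutated,
carry offset gene properties, and attach preferentially (hub bias) in the
scale-free interaction graph.  Every signal channel can be nulled
independently, which is how leakage and ablation behaviour are probed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CohortData,
    LabelCatalogue,
    PPITable,
    SystemFeatureTable,
    write_labels,
    write_matrix,
    write_ppi,
    write_system_features,
)

logger = logging.getLogger("drivergcn")


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Defaults plant a clearly recoverable multi-omics driver signal in a
    desk-scale cohort: 20 tumor samples x 300 genes with 30 drivers that
    mutate at 40% (vs 2% background), gain +3 log2 expression and +0.2
    methylation in mutated samples, carry copy-number events at 30%, have
    gene properties offset by +1 SD, and are 3x stickier in the
    preferential-attachment interaction graph.
    """

    n_samples: int = 20
    n_genes: int = 300
    n_drivers: int = 30
    n_controls: int = 20
    # interaction graph (preferential attachment)
    ppi_edges_per_node: int = 3
    driver_hub_boost: float = 3.0
    # mutation
    driver_mutation_rate: float = 0.4
    background_mutation_rate: float = 0.02
    # per-channel driver effects in mutated samples
    expression_shift: float = 3.0
    methylation_shift: float = 0.2
    cnv_driver_prob: float = 0.3
    cnv_background_prob: float = 0.05
    system_feature_offset: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_drivers >= self.n_genes:
            raise ValueError("n_drivers must be < n_genes")
        if self.ppi_edges_per_node >= self.n_genes:
            raise ValueError("ppi_edges_per_node must be < n_genes")
        for name in ("driver_mutation_rate", "background_mutation_rate"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def null(cls, seed: int = 0) -> "SimulationConfig":
        """All driver signal removed: equal mutation rates, no shifts, no
        hub bias — drivers are statistically indistinguishable."""
        return cls(
            driver_hub_boost=1.0,
            driver_mutation_rate=0.1,
            background_mutation_rate=0.1,
            expression_shift=0.0,
            methylation_shift=0.0,
            cnv_driver_prob=0.05,
            system_feature_offset=0.0,
            seed=seed,
        )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort."""

    driver_genes: list[str]
    mutated_drivers_per_sample: dict[str, list[str]]
    config: SimulationConfig


@dataclass
class SyntheticCohort:
    cohort: CohortData
    ppi: PPITable
    system_table: SystemFeatureTable
    labels: LabelCatalogue | None  # None when n_drivers == 0
    truth: SyntheticTruth


def _preferential_attachment(
    genes: list[str], drivers: set[str], m: int, boost: float, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Scale-free graph: each new node attaches to m existing nodes chosen
    with probability proportional to (degree + 1) * boost-if-driver."""
    order = list(rng.permutation(genes))
    degree = {g: 0 for g in genes}
    edges: set[tuple[str, str]] = set()
    for t in range(m, len(order)):
        new = order[t]
        pool = order[:t]
        w = np.array(
            [(degree[g] + 1.0) * (boost if g in drivers else 1.0) for g in pool]
        )
        targets = rng.choice(len(pool), size=m, replace=False, p=w / w.sum())
        for j in targets:
            g = pool[j]
            edges.add((new, g) if new < g else (g, new))
            degree[new] += 1
            degree[g] += 1
    # connect the m seed nodes among themselves
    for i in range(m):
        for j in range(i + 1, m):
            a, b = order[i], order[j]
            edges.add((a, b) if a < b else (b, a))
    return sorted(edges)


def simulate(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort bundle, reproducible from `config.seed`."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    controls = [f"C{i:03d}" for i in range(config.n_controls)]
    drivers = sorted(rng.choice(genes, size=config.n_drivers, replace=False).tolist())
    driver_set = set(drivers)
    is_driver = np.array([g in driver_set for g in genes])

    # (a) interaction graph
    edges = _preferential_attachment(
        genes, driver_set, config.ppi_edges_per_node, config.driver_hub_boost, rng
    )
    ppi = PPITable(
        edges=pd.DataFrame(
            {
                "gene_a": [a for a, _ in edges],
                "gene_b": [b for _, b in edges],
                "score": np.round(rng.uniform(700, 999, size=len(edges)), 1),
            }
        ),
        score_threshold=700.0,
    )

    # (b) mutations
    rates = np.where(
        is_driver, config.driver_mutation_rate, config.background_mutation_rate
    )
    mutation = (rng.random((config.n_samples, config.n_genes)) < rates).astype(int)
    mutated_driver = mutation.astype(bool) & is_driver  # samples x genes

    # (c) expression: per-gene baseline + driver shift in mutated samples
    baseline = rng.normal(6.0, 1.0, size=config.n_genes)
    expression = (
        baseline
        + config.expression_shift * mutated_driver
        + rng.normal(0, config.noise_sd, size=(config.n_samples, config.n_genes))
    )
    control_expression = baseline + rng.normal(
        0, config.noise_sd, size=(config.n_controls, config.n_genes)
    )

    # (d) methylation: Beta-distributed baseline, shifted where driver mutated
    meth_base = rng.beta(2.0, 2.0, size=config.n_genes)
    methylation = np.clip(
        meth_base
        + config.methylation_shift * mutated_driver
        + rng.normal(0, 0.05, size=(config.n_samples, config.n_genes)),
        0.0,
        1.0,
    )

    # (e) copy number: categorical events, enriched for mutated drivers
    event_prob = np.where(
        mutated_driver, config.cnv_driver_prob, config.cnv_background_prob
    )
    has_event = rng.random((config.n_samples, config.n_genes)) < event_prob
    categories = rng.choice(
        [-2, -1, 1, 2], size=(config.n_samples, config.n_genes)
    )
    cnv = np.where(has_event, categories, 0)

    # (f) gene properties: 18 standard-normal columns, drivers offset
    sysfeat = rng.normal(0, 1, size=(config.n_genes, 18))
    sysfeat += config.system_feature_offset * is_driver[:, None]

    def frame(mat, index):
        return pd.DataFrame(mat, index=index, columns=genes)

    cohort = CohortData(
        mutation=frame(mutation, samples),
        expression=frame(np.round(expression, 4), samples),
        methylation=frame(np.round(methylation, 4), samples),
        cnv=frame(cnv, samples).astype(int),
        control_expression=frame(np.round(control_expression, 4), controls),
    )
    system_table = SystemFeatureTable(
        features=pd.DataFrame(
            np.round(sysfeat, 4),
            index=pd.Index(genes, name="gene"),
            columns=[f"sysfeat_{i:02d}" for i in range(1, 19)],
        )
    )
    labels = LabelCatalogue(positive_genes=frozenset(drivers)) if drivers else None
    truth = SyntheticTruth(
        driver_genes=drivers,
        mutated_drivers_per_sample={
            s: sorted(np.array(genes)[mutated_driver[i]].tolist())
            for i, s in enumerate(samples)
        },
        config=config,
    )
    logger.info(
        "simulated cohort: %d samples, %d genes, %d drivers, %d PPI edges",
        config.n_samples, config.n_genes, config.n_drivers, len(edges),
    )
    return SyntheticCohort(
        cohort=cohort, ppi=ppi, system_table=system_table, labels=labels, truth=truth
    )


FILENAMES = {
    "mutation": "mutation.tsv",
    "expression": "expression.tsv",
    "methylation": "methylation.tsv",
    "cnv": "cnv.tsv",
    "control_expression": "control_expression.tsv",
    "ppi": "ppi.tsv",
    "system_features": "system_features.tsv",
    "labels": "drivers.txt",
    "truth": "truth.json",
}


def write(bundle: SyntheticCohort, directory: str | Path) -> dict[str, str]:
    """Persist the bundle in the exact formats the loaders read; returns a
    manifest of written files with their shapes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    c = bundle.cohort
    manifest: dict[str, dict] = {}
    for key, df in {
        "mutation": c.mutation,
        "expression": c.expression,
        "methylation": c.methylation,
        "cnv": c.cnv,
        "control_expression": c.control_expression,
    }.items():
        write_matrix(df, directory / FILENAMES[key])
        manifest[FILENAMES[key]] = {"rows": df.shape[0], "columns": df.shape[1]}
    write_ppi(bundle.ppi, directory / FILENAMES["ppi"])
    manifest[FILENAMES["ppi"]] = {"rows": len(bundle.ppi.edges), "columns": 3}
    write_system_features(bundle.system_table, directory / FILENAMES["system_features"])
    manifest[FILENAMES["system_features"]] = {
        "rows": bundle.system_table.features.shape[0],
        "columns": bundle.system_table.features.shape[1],
    }
    genes = bundle.truth.driver_genes
    write_labels(set(genes), directory / FILENAMES["labels"])
    manifest[FILENAMES["labels"]] = {"rows": len(genes), "columns": 1}
    with open(directory / FILENAMES["truth"], "w") as fh:
        json.dump(
            {
                "driver_genes": bundle.truth.driver_genes,
                "mutated_drivers_per_sample": bundle.truth.mutated_drivers_per_sample,
                "config": dataclasses.asdict(bundle.truth.config),
            },
            fh,
            indent=2,
        )
    manifest[FILENAMES["truth"]] = {"rows": 1, "columns": 1}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {k: str(directory / v) for k, v in FILENAMES.items()}
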