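"""Scoring, ranking and benchmark reports.

Node scores become per-sample ranked gene lists (descending score, ties
broken lexicographically) and a population-level gene ranking (per-gene
aggregate over that gene's sample nodes, max by default).  Reports cover
classification metrics on held-out nodes (accuracy / ROC AUC / area under
the precision-recall curve), top-k precision/recall/F1 against a
reference driver catalogue, per-sample top-k reference hits, and flags
for rare drivers — genes ranked in a sample's top-k that are mutated in
fewer than 2% of the cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .network import InteractionGraph

logger = logging.getLogger("drivergcn")


@dataclass
class PredictionResult:
    """Per-node scores with derived per-sample and population rankings."""

    graph: InteractionGraph
    scores: np.ndarray  # (n_nodes,) in (0, 1)
    sample_rankings: dict[str, list[tuple[str, float]]] = field(init=False)
    population_ranking: list[tuple[str, float]] = field(init=False)
    aggregate: str = "max"

    def __post_init__(self) -> None:
        self.sample_rankings = rank_sample_genes(self.graph, self.scores)
        self.population_ranking = rank_population_genes(
            self.graph, self.scores, aggregate=self.aggregate
        )


def rank_sample_genes(
    graph: InteractionGraph, scores: np.ndarray
) -> dict[str, list[tuple[str, float]]]:
    """Per-sample gene lists sorted by descending score, ties lexicographic."""
    per_sample: dict[str, list[tuple[str, float]]] = {}
    for s, g, sc in zip(graph.node_samples, graph.node_genes, scores):
        per_sample.setdefault(s, []).append((g, float(sc)))
    return {
        s: sorted(items, key=lambda t: (-t[1], t[0]))
        for s, items in per_sample.items()
    }


def rank_population_genes(
    graph: InteractionGraph, scores: np.ndarray, aggregate: str = "max"
) -> list[tuple[str, float]]:
    """Cohort-level ranking: per-gene max (default) or mean over its nodes."""
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    acc: dict[str, list[float]] = {}
    for g, sc in zip(graph.node_genes, scores):
        acc.setdefault(g, []).append(float(sc))
    agg = {g: (max(v) if aggregate == "max" else float(np.mean(v))) for g, v in acc.items()}
    return sorted(agg.items(), key=lambda t: (-t[1], t[0]))


def compute_metrics(
    scores, labels, mask=None, threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy at `threshold`, ROC AUC (trapezoidal) and AUPR (step
    interpolation) over masked nodes."""
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels, int).ravel()
    if mask is not None:
        mask = np.asarray(mask, bool)
        scores, labels = scores[mask], labels[mask]
    if len(np.unique(labels)) < 2:
        raise ValueError("metrics undefined: mask holds a single class")
    acc = float(((scores >= threshold).astype(int) == labels).mean())
    return {
        "acc": acc,
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
    }


def topk_overlap(
    ranked_genes: Sequence[str], reference: Iterable[str], k: int
) -> tuple[float, float, float]:
    """Precision / recall / F1 of the top-k of a ranked gene list against a
    reference catalogue; F1 defined as 0 when P = R = 0."""
    reference = {g.upper() for g in reference}
    if not reference:
        raise ValueError("reference gene set is empty")
    if k > len(ranked_genes):
        raise ValueError(f"k={k} exceeds ranked list length {len(ranked_genes)}")
    hits = len({g.upper() for g in ranked_genes[:k]} & reference)
    precision = hits / k
    recall = hits / len(reference)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def per_sample_hits(
    result: PredictionResult, reference: Iterable[str], k_list: Sequence[int] = (50, 100)
) -> pd.DataFrame:
    """For each sample and each k, the number of top-k genes found in the
    reference catalogue; samples shorter than k use their full list."""
    reference = {g.upper() for g in reference}
    rows = []
    for sample, ranking in sorted(result.sample_rankings.items()):
        genes = [g for g, _ in ranking]
        row: dict[str, object] = {"sample_id": sample, "n_genes": len(genes)}
        for k in k_list:
            if len(genes) < k:
                logger.info(
                    "sample %s has %d < %d genes; full list used", sample, len(genes), k
                )
            row[f"hits_top{k}"] = len(set(genes[:k]) & reference)
        rows.append(row)
    return pd.DataFrame(rows)


def flag_rare_drivers(
    result: PredictionResult,
    mutation: pd.DataFrame,
    frequency_threshold: float = 0.02,
    k: int = 50,
) -> pd.DataFrame:
    """Flag genes ranked in any sample's top-k whose cohort mutation
    frequency is below `frequency_threshold` (and that are mutated in at
    least one sample — a rare driver still requires a mutation)."""
    n_samples = len(mutation)
    freq = mutation.sum(axis=0) / n_samples
    rows = []
    seen: dict[str, list[str]] = {}
    for sample, ranking in sorted(result.sample_rankings.items()):
        for g, _ in ranking[:k]:
            seen.setdefault(g, []).append(sample)
    for gene in sorted(seen):
        f = float(freq.get(gene, 0.0))
        mutated = bool(gene in mutation.columns and mutation[gene].sum() > 0)
        rows.append(
            {
                "gene": gene,
                "mutation_frequency": f,
                "n_samples_topk": len(seen[gene]),
                "samples_topk": ",".join(seen[gene]),
                "rare": bool(mutated and f < frequency_threshold),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------


def write_reports(
    directory: str | Path,
    result: PredictionResult,
    metrics: Mapping[str, float] | None = None,
    hits: pd.DataFrame | None = None,
    rare: pd.DataFrame | None = None,
    extra_summary: Mapping | None = None,
) -> None:
    """Write rankings + metric tables as TSV and a JSON summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [
        {"sample_id": s, "rank": i + 1, "gene": g, "score": f"{sc:.6f}"}
        for s, ranking in sorted(result.sample_rankings.items())
        for i, (g, sc) in enumerate(ranking)
    ]
    pd.DataFrame(rows).to_csv(directory / "rankings.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene": g, "score": f"{sc:.6f}"} for g, sc in result.population_ranking]
    ).to_csv(directory / "population_ranking.tsv", sep="\t", index=False)
    summary: dict = dict(extra_summary or {})
    if metrics is not None:
        pd.DataFrame([metrics]).to_csv(directory / "metrics.tsv", sep="\t", index=False)
        summary["metrics"] = dict(metrics)
    if hits is not None:
        hits.to_csv(directory / "per_sample_hits.tsv", sep="\t", index=False)
    if rare is not None:
        rare.to_csv(directory / "rare_drivers.tsv", sep="\t", index=False)
        summary["n_rare_drivers"] = int(rare["rare"].sum()) if len(rare) else 0
    with open(directory / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
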