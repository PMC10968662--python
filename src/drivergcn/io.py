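"""Readers and writers for cohort omics matrices, interaction tables,
system-level gene properties and driver-gene label lists.

All tabular formats are tab-separated UTF-8 with a mandatory header row.
Omics matrices have samples as rows (first column = sample ID) and genes
as columns; interaction tables are three columns (geneA, geneB, score);
gene lists are one symbol per line.  Symbols are matched uppercase-exact;
no alias resolution is attempted.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("drivergcn")

OMICS_KEYS = ("mutation", "expression", "methylation", "cnv")
CNV_CATEGORIES = frozenset({-2, -1, 0, 1, 2})


def setup_logging(level: str = "INFO", logfile: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CohortData:
    """Aligned samples x genes multi-omics matrices for one cohort.

    `mutation` is binary (1 = non-silent mutation), `expression` is
    log2-scale, `methylation` holds beta values in [0, 1], `cnv` holds
    discrete copy-number categories in {-2,...,2}.  An optional
    `control_expression` matrix (control samples x same genes) supports
    differential-expression calling.
    """

    mutation: pd.DataFrame
    expression: pd.DataFrame
    methylation: pd.DataFrame
    cnv: pd.DataFrame
    control_expression: Optional[pd.DataFrame] = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mutation.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mutation.columns)

    def validate(self) -> None:
        frames = {
            "mutation": self.mutation,
            "expression": self.expression,
            "methylation": self.methylation,
            "cnv": self.cnv,
        }
        ref = self.mutation
        if ref.index.has_duplicates or ref.columns.has_duplicates:
            raise ValueError("duplicate sample or gene identifiers")
        for name, df in frames.items():
            if list(df.index) != list(ref.index) or list(df.columns) != list(ref.columns):
                raise ValueError(f"{name} matrix is not aligned with mutation matrix")
            if df.isna().any().any():
                raise ValueError(f"{name} matrix contains missing values")
        _check_domain("mutation", self.mutation, lambda v: np.isin(v, (0, 1)))
        _check_domain("methylation", self.methylation, lambda v: (v >= 0) & (v <= 1))
        _check_domain("cnv", self.cnv, lambda v: np.isin(v, sorted(CNV_CATEGORIES)))
        if self.control_expression is not None:
            missing = set(ref.columns) - set(self.control_expression.columns)
            if missing:
                raise ValueError(
                    f"control expression lacks {len(missing)} cohort genes"
                )


@dataclass
class PPITable:
    """Undirected, deduplicated gene-gene interaction edges with scores."""

    edges: pd.DataFrame  # columns: gene_a, gene_b, score
    score_threshold: float

    def __len__(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return {
            tuple(sorted((a, b)))
            for a, b in zip(self.edges["gene_a"], self.edges["gene_b"])
        }


@dataclass
class SystemFeatureTable:
    """Global per-gene properties (18 columns: gene length, domain count,
    gene age, essentiality, ...)."""

    features: pd.DataFrame  # index: gene symbols, 18 feature columns

    N_FEATURES = 18

    def __post_init__(self) -> None:
        if self.features.shape[1] != self.N_FEATURES:
            raise ValueError(
                f"system feature table must have exactly {self.N_FEATURES} "
                f"columns, got {self.features.shape[1]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)


@dataclass
class LabelCatalogue:
    """Union of known driver-gene lists; the positive class."""

    positive_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positive_genes:
            raise ValueError("label catalogue is empty")
        self.positive_genes = frozenset(g.upper() for g in self.positive_genes)


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def _check_domain(name, df, predicate) -> None:
    vals = df.to_numpy()
    ok = predicate(vals)
    if not ok.all():
        bad_idx = np.argwhere(~ok)[:5]
        offenders = [
            f"({df.index[i]}, {df.columns[j]}) = {vals[i, j]!r}" for i, j in bad_idx
        ]
        raise ValueError(f"{name} matrix has out-of-range values: {offenders}")


def _read_matrix(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"{path}: matrix contains missing (NA) values")
    df.index = df.index.astype(str)
    df.columns = [str(c).upper() for c in df.columns]
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample identifiers")
    if pd.Index(df.columns).has_duplicates:
        raise ValueError(f"{path}: duplicate gene identifiers")
    return df


def load_cohort(
    paths: Mapping[str, str | Path],
    keep_genes: Iterable[str] | None = None,
) -> CohortData:
    """Load the four tumor omics matrices (plus optional controls).

    Matrices are aligned to the intersection of samples present in all
    omics files and the intersection of genes across files (including the
    control matrix when given); both orderings are lexicographic.
    `keep_genes` optionally restricts the gene universe (e.g. to coding
    genes) instead of any heuristic filter.
    """
    missing = [k for k in OMICS_KEYS if k not in paths]
    if missing:
        raise ValueError(f"missing omics paths: {missing}")
    frames = {k: _read_matrix(paths[k]) for k in OMICS_KEYS}
    control = _read_matrix(paths["control_expression"]) if paths.get(
        "control_expression"
    ) else None

    samples: set[str] = set(frames["mutation"].index)
    genes: set[str] = set(frames["mutation"].columns)
    for k in OMICS_KEYS[1:]:
        samples &= set(frames[k].index)
        genes &= set(frames[k].columns)
    if control is not None:
        genes &= set(control.columns)
    if keep_genes is not None:
        genes &= {g.upper() for g in keep_genes}
    if not samples:
        raise ValueError("no common samples across omics files")
    if not genes:
        raise ValueError("no common genes across omics files")
    sample_order = sorted(samples)
    gene_order = sorted(genes)

    aligned = {k: frames[k].loc[sample_order, gene_order] for k in OMICS_KEYS}
    aligned["cnv"] = aligned["cnv"].astype(int)
    aligned["mutation"] = aligned["mutation"].astype(int)
    cohort = CohortData(
        control_expression=(
            control.loc[sorted(control.index), gene_order] if control is not None else None
        ),
        **aligned,
    )
    cohort.validate()
    logger.info(
        "loaded cohort: %d samples x %d genes%s",
        len(sample_order),
        len(gene_order),
        "" if control is None else f", {len(control)} controls",
    )
    return cohort


def load_ppi(path: str | Path, score_threshold: float = 700.0) -> PPITable:
    """Load a STRING-style 3-column edge list, dropping self-edges,
    sub-threshold edges and undirected duplicates."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        logger.warning("PPI file %s is empty", path)
        return PPITable(
            edges=pd.DataFrame(columns=["gene_a", "gene_b", "score"]),
            score_threshold=score_threshold,
        )
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (geneA, geneB, score)")
    df = df.iloc[:, :3]
    df.columns = ["gene_a", "gene_b", "score"]
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    df["gene_a"] = df["gene_a"].astype(str).str.upper()
    df["gene_b"] = df["gene_b"].astype(str).str.upper()
    df = df[df["score"] >= score_threshold]
    df = df[df["gene_a"] != df["gene_b"]]
    key = df.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    df = df.assign(_key=key).drop_duplicates("_key").drop(columns="_key")
    df = df.reset_index(drop=True)
    logger.info("loaded %d PPI edges (threshold %.0f)", len(df), score_threshold)
    return PPITable(edges=df, score_threshold=score_threshold)


def load_system_features(path: str | Path) -> SystemFeatureTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.upper()
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene identifiers")
    return SystemFeatureTable(features=df.astype(float))


def load_labels(paths: Iterable[str | Path]) -> LabelCatalogue:
    """Union of one-symbol-per-line driver-gene lists, uppercased."""
    genes: set[str] = set()
    for p in paths:
        with open(p) as fh:
            genes |= {line.strip().upper() for line in fh if line.strip()}
    if not genes:
        raise ValueError("all label files are empty")
    logger.info("loaded %d positive genes", len(genes))
    return LabelCatalogue(positive_genes=frozenset(genes))


# ---------------------------------------------------------------------------
# writers (round-trip counterparts; also used by the cohort simulator)
# ---------------------------------------------------------------------------


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def write_ppi(ppi: PPITable, path: str | Path) -> None:
    ppi.edges.to_csv(path, sep="\t", index=False)


def write_system_features(table: SystemFeatureTable, path: str | Path) -> None:
    table.features.to_csv(path, sep="\t", index_label="gene")


def write_labels(catalogue_or_genes, path: str | Path) -> None:
    genes = (
        catalogue_or_genes.positive_genes
        if isinstance(catalogue_or_genes, LabelCatalogue)
        else catalogue_or_genes
    )
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
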