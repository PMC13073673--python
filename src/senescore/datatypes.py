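"""Core containers for the ensemble-of-gene-sets (EGS) senescence scoring pipeline.

The pipeline works on genes × cells matrices. Counts are kept sparse; the
log-normalized layer is dense (datasets handled here are a few thousand cells).
All gene symbols are upper-cased at ingest so cell-line and tissue panels with
different case conventions join cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

SCHEMA_VERSION = 1

LOWSASP_TAG = "lowSASP"


class ContractError(ValueError):
    """A caller violated a documented precondition."""


class FormatError(ValueError):
    """An input file does not conform to its declared format."""


@dataclass
class EgsParams:
    """Tunable parameters of the EGS pipeline.

    z_high
        z-score above which a cell counts as a high expresser of a driver gene.
    min_cells
        minimum number of high-expresser cells required to build a gene-set pair.
    logfc_threshold
        minimum |log2 fold change| for a gene to enter differential testing.
    adj_p_max
        Bonferroni-adjusted p-value cutoff for retaining a marker gene.
    scale_factor
        library-size scale factor of the log-normalization.
    n_confident
        number of cells selected per confident stratum (lowest / highest scores).
    k_folds
        folds of the cross-validation.
    min_coverage
        minimum fraction of a pair's genes that must be present in a dataset for
        the pair to be scored there (guards transfer to gene-poor panels).
    lowsasp_quantile
        group quantile of the SASP nonzero-fraction below which a cell is a
        candidate "low SASP" cell.
    """

    z_high: float = 1.5
    min_cells: int = 50
    logfc_threshold: float = 0.25
    adj_p_max: float = 0.05
    scale_factor: float = 10_000.0
    n_confident: int = 100
    k_folds: int = 3
    rng_seed: int = 0
    min_coverage: float = 0.3
    lowsasp_quantile: float = 0.25

    def __post_init__(self) -> None:
        if not self.z_high > 0:
            raise ContractError("z_high must be > 0")
        if self.min_cells < 2:
            raise ContractError("min_cells must be >= 2")
        if not (0 < self.adj_p_max <= 1):
            raise ContractError("adj_p_max must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EgsParams":
        return cls(**d)


class ExpressionDataset:
    """Genes × cells expression dataset with raw counts and an optional
    log-normalized layer.

    Invariants: gene and cell identifiers are unique; ``lognorm``, when present,
    has the same shape as ``counts`` and is zero exactly where counts are zero.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        cell_ids: Sequence[str],
        counts: sp.spmatrix | np.ndarray,
        cell_meta: Optional[pd.DataFrame] = None,
        lognorm: Optional[np.ndarray] = None,
    ) -> None:
        gene_ids = [str(g).upper() for g in gene_ids]
        cell_ids = [str(c) for c in cell_ids]
        if len(set(gene_ids)) != len(gene_ids):
            raise ContractError("gene_ids must be unique (collapse duplicates first)")
        if len(set(cell_ids)) != len(cell_ids):
            raise ContractError("cell_ids must be unique")
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(gene_ids), len(cell_ids)):
            raise ContractError(
                f"counts shape {counts.shape} does not match "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells"
            )
        if counts.nnz and counts.data.min() < 0:
            raise ContractError("counts must be non-negative")
        if cell_meta is None:
            cell_meta = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
        else:
            cell_meta = cell_meta.copy()
            cell_meta.index = pd.Index([str(c) for c in cell_meta.index], name="cell_id")
            cell_meta = cell_meta.loc[cell_ids]
        if lognorm is not None:
            lognorm = np.asarray(lognorm, dtype=float)
            if lognorm.shape != counts.shape:
                raise ContractError("lognorm shape must match counts shape")
        self.gene_ids = gene_ids
        self.cell_ids = cell_ids
        self.counts = counts
        self.cell_meta = cell_meta
        self.lognorm = lognorm
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(cell_ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene.upper()]
        except KeyError:
            raise ContractError(f"gene {gene!r} not in dataset") from None

    def has_gene(self, gene: str) -> bool:
        return gene.upper() in self._gene_index

    def cell_indices(self, cell_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._cell_index[c] for c in cell_ids], dtype=int)
        except KeyError as e:
            raise ContractError(f"cell {e.args[0]!r} not in dataset") from None

    def cells_of_group(self, group_label: str) -> list[str]:
        if "group_label" not in self.cell_meta.columns:
            raise ContractError("cell_meta has no group_label column")
        mask = self.cell_meta["group_label"].to_numpy() == group_label
        if not mask.any():
            raise ContractError(f"unknown group {group_label!r}")
        return [c for c, m in zip(self.cell_ids, mask) if m]

    def require_lognorm(self) -> np.ndarray:
        if self.lognorm is None:
            raise ContractError("lognorm layer absent; run lognormalize first")
        return self.lognorm

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionDataset":
        idx = self.cell_indices(cell_ids)
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in idx],
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta.iloc[idx],
            lognorm=None if self.lognorm is None else self.lognorm[:, idx],
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        idx = np.array([self.gene_index(g) for g in gene_ids], dtype=int)
        return ExpressionDataset(
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=self.cell_ids,
            counts=self.counts[idx, :],
            cell_meta=self.cell_meta,
            lognorm=None if self.lognorm is None else self.lognorm[idx, :],
        )

    def __repr__(self) -> str:  # pragma: no cover
        layers = "counts" + (", lognorm" if self.lognorm is not None else "")
        return f"ExpressionDataset({self.n_genes} genes x {self.n_cells} cells; {layers})"


@dataclass
class GeneSetPair:
    """One up/down gene-set pair conditioned on a driver gene (or the lowSASP tag)."""

    driver: str
    group: str
    up_genes: list[str]
    down_genes: list[str]
    n_driver_cells: int

    def __post_init__(self) -> None:
        self.up_genes = sorted({g.upper() for g in self.up_genes})
        self.down_genes = sorted({g.upper() for g in self.down_genes})
        if set(self.up_genes) & set(self.down_genes):
            raise ContractError("up_genes and down_genes must be disjoint")
        if not (self.up_genes or self.down_genes):
            raise ContractError("a pair must have at least one gene")

    @property
    def label(self) -> str:
        return f"{self.driver}@{self.group}"

    @property
    def genes(self) -> list[str]:
        return self.up_genes + self.down_genes


@dataclass
class ReferenceStats:
    """Per-gene mean/SD of the log-normalized control cells, frozen at build time."""

    gene_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_control_cells: int

    def __post_init__(self) -> None:
        self.gene_ids = [g.upper() for g in self.gene_ids]
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.gene_ids) == self.mean.size == self.sd.size):
            raise ContractError("gene_ids, mean, sd must have equal lengths")
        if self.sd.size and self.sd.min() < 0:
            raise ContractError("sd must be non-negative")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self._index

    def index(self, gene: str) -> int:
        try:
            return self._index[gene.upper()]
        except KeyError:
            raise ContractError(f"gene {gene!r} not in reference stats") from None


@dataclass
class EnsembleModel:
    """The full ensemble: gene-set pairs plus the frozen reference statistics."""

    pairs: list[GeneSetPair]
    ref_stats: ReferenceStats
    params: EgsParams
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        for pair in self.pairs:
            for g in pair.genes:
                if g not in self.ref_stats:
                    raise ContractError(
                        f"pair {pair.label}: gene {g} missing from reference stats"
                    )

    # -- JSON serialization ---------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "params": self.params.to_dict(),
            "ref_stats": {
                "gene_ids": self.ref_stats.gene_ids,
                "mean": self.ref_stats.mean.tolist(),
                "sd": self.ref_stats.sd.tolist(),
                "n_control_cells": self.ref_stats.n_control_cells,
            },
            "pairs": [
                {
                    "driver": p.driver,
                    "group": p.group,
                    "up_genes": p.up_genes,
                    "down_genes": p.down_genes,
                    "n_driver_cells": p.n_driver_cells,
                }
                for p in self.pairs
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            pairs=[GeneSetPair(**p) for p in d["pairs"]],
            ref_stats=ReferenceStats(
                gene_ids=d["ref_stats"]["gene_ids"],
                mean=np.array(d["ref_stats"]["mean"]),
                sd=np.array(d["ref_stats"]["sd"]),
                n_control_cells=d["ref_stats"]["n_control_cells"],
            ),
            params=EgsParams.from_dict(d["params"]),
            schema_version=d.get("schema_version", SCHEMA_VERSION),
        )

    @classmethod
    def from_json(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ClassifierFit:
    """Two-Gaussian score model with a decision threshold."""

    mu_ctrl: float
    sd_ctrl: float
    n_ctrl: int
    mu_sen: float
    sd_sen: float
    n_sen: int
    threshold: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierFit":
        return cls(**d)


@dataclass
class ConfidentSelection:
    """The n lowest-score p21-/p16- cells and n highest-score p21+ or p16+ cells."""

    low_cells: list[str]
    high_cells: list[str]
    n: int

    def __post_init__(self) -> None:
        if set(self.low_cells) & set(self.high_cells):
            raise ContractError("confident strata must be disjoint")


@dataclass
class ScoreVector:
    """Per-cell pair scores and their signed-extremum aggregate."""

    cell_id: str
    per_pair_scores: np.ndarray
    egs_score: float


@dataclass
class ProliferationResult:
    """Cell-cycle signature scores; a positive score marks a cycling cell."""

    cell_ids: list[str]
    score: np.ndarray
    s_score: np.ndarray
    g2m_score: np.ndarray

    @property
    def is_proliferative(self) -> np.ndarray:
        return self.score > 0
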