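"""Normalization, reference z-scoring, proliferation scoring, and group splitting.

The reference z-score is the pipeline's working coordinate system: every gene is
standardized against the mean/SD of the proliferating control cells, so a z of
1.5 always means "1.5 control SDs above the control mean", in any group or
tissue scored against the same frozen reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import (
    ContractError,
    ExpressionDataset,
    ProliferationResult,
    ReferenceStats,
)

log = logging.getLogger(__name__)


def lognormalize(dataset: ExpressionDataset, scale_factor: float = 10_000.0) -> ExpressionDataset:
    """Attach the log-normalized layer: ln(1 + count * scale_factor / cell_total).

    Cells with a zero total count are dropped with a warning (they cannot be
    normalized). Returns a dataset carrying both layers.
    """
    totals = np.asarray(dataset.counts.sum(axis=0)).ravel()
    keep = totals > 0
    if not keep.all():
        dropped = [c for c, k in zip(dataset.cell_ids, keep) if not k]
        log.warning("dropping %d zero-total cell(s): %s", len(dropped), dropped[:5])
        dataset = dataset.subset_cells([c for c, k in zip(dataset.cell_ids, keep) if k])
        totals = totals[keep]
    dense = np.asarray(dataset.counts.todense(), dtype=float)
    lognorm = np.log1p(dense * (scale_factor / totals)[None, :])
    return ExpressionDataset(
        gene_ids=dataset.gene_ids,
        cell_ids=dataset.cell_ids,
        counts=dataset.counts,
        cell_meta=dataset.cell_meta,
        lognorm=lognorm,
    )


def compute_reference_stats(
    dataset: ExpressionDataset, control_cell_ids: Sequence[str]
) -> ReferenceStats:
    """Per-gene mean and SD (denominator n-1) of the log-normalized control cells."""
    X = dataset.require_lognorm()
    idx = dataset.cell_indices(control_cell_ids)
    if idx.size < 2:
        raise ContractError("need at least 2 control cells for reference stats")
    ctrl = X[:, idx]
    return ReferenceStats(
        gene_ids=list(dataset.gene_ids),
        mean=ctrl.mean(axis=1),
        sd=ctrl.std(axis=1, ddof=1),
        n_control_cells=idx.size,
    )


@dataclass
class ZMatrix:
    """Reference z-scores for the genes a dataset shares with a ReferenceStats.

    Genes whose reference SD is zero get a z row of exactly 0 and are flagged
    unusable as drivers (``sd_zero``).
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    sd_zero: np.ndarray

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def has_gene(self, gene: str) -> bool:
        return gene.upper() in self._index

    def gene_index(self, gene: str) -> int:
        try:
            return self._index[gene.upper()]
        except KeyError:
            raise ContractError(f"gene {gene!r} not covered by reference stats") from None

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def is_usable_driver(self, gene: str) -> bool:
        return self.has_gene(gene) and not self.sd_zero[self.gene_index(gene)]


def zscore_matrix(dataset: ExpressionDataset, ref_stats: ReferenceStats) -> ZMatrix:
    """Standardize the lognorm layer against frozen reference mean/SD.

    Only genes present in both the dataset and the reference are covered;
    accessing any other gene through the result raises a ContractError.
    """
    X = dataset.require_lognorm()
    shared = [g for g in dataset.gene_ids if g in ref_stats]
    ds_idx = np.array([dataset.gene_index(g) for g in shared], dtype=int)
    rs_idx = np.array([ref_stats.index(g) for g in shared], dtype=int)
    mean = ref_stats.mean[rs_idx]
    sd = ref_stats.sd[rs_idx]
    sd_zero = sd == 0
    safe_sd = np.where(sd_zero, 1.0, sd)
    z = (X[ds_idx, :] - mean[:, None]) / safe_sd[:, None]
    z[sd_zero, :] = 0.0
    return ZMatrix(gene_ids=shared, cell_ids=list(dataset.cell_ids), values=z, sd_zero=sd_zero)


# -- bin-matched signature scoring --------------------------------------

def binned_control_score(
    dataset: ExpressionDataset,
    signature_genes: Sequence[str],
    n_bins: int = 24,
    n_ctrl_per_gene: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean lognorm of signature genes minus mean lognorm of expression-bin-matched
    control genes (one pooled control set, sampled per signature gene with a
    fixed seed).

    Bins are equal-occupancy over the per-gene mean expression of all genes.
    Control genes are sampled from the signature gene's bin excluding the
    signature itself; if a bin holds no non-signature gene the whole bin is used.
    """
    X = dataset.require_lognorm()
    if rng is None:
        rng = np.random.default_rng(0)
    sig = sorted({g.upper() for g in signature_genes if dataset.has_gene(g)})
    if not sig:
        raise ContractError("no signature gene present in dataset")
    sig_idx = np.array([dataset.gene_index(g) for g in sig])

    # equal-occupancy bins over per-gene mean expression; the secondary sort on
    # gene name makes binning and control sampling invariant to row order
    gene_means = X.mean(axis=1)
    names = np.array(dataset.gene_ids)
    order = np.lexsort((names, gene_means))
    bins = np.empty(dataset.n_genes, dtype=int)
    bins[order] = np.floor(
        np.arange(dataset.n_genes) * n_bins / dataset.n_genes
    ).astype(int)

    sig_set = set(sig_idx.tolist())
    ctrl_pool: set[int] = set()
    for gi in sig_idx:
        bin_members = np.flatnonzero(bins == bins[gi])
        eligible = [i for i in bin_members if i not in sig_set] or list(bin_members)
        eligible = sorted(eligible, key=lambda i: names[i])
        take = min(n_ctrl_per_gene, len(eligible))
        ctrl_pool.update(
            rng.choice(np.array(eligible), size=take, replace=False).tolist()
        )
    ctrl_idx = np.array(sorted(ctrl_pool), dtype=int)
    return X[sig_idx].mean(axis=0) - X[ctrl_idx].mean(axis=0)


def proliferation_score(
    dataset: ExpressionDataset,
    s_genes: Sequence[str],
    g2m_genes: Sequence[str],
    n_bins: int = 24,
    n_ctrl_per_gene: int = 100,
    rng_seed: int = 0,
) -> ProliferationResult:
    """Cell-cycle proliferation score: max of the S-phase and G2/M bin-matched
    signature scores; a cell is proliferative iff its score is positive
    (senescent cells are G1-arrested and score at or below zero).
    """
    s_present = [g for g in s_genes if dataset.has_gene(g)]
    g2m_present = [g for g in g2m_genes if dataset.has_gene(g)]
    if not s_present or not g2m_present:
        raise ContractError("need at least one S gene and one G2/M gene in the dataset")
    rng = np.random.default_rng(rng_seed)
    s_score = binned_control_score(dataset, s_present, n_bins, n_ctrl_per_gene, rng)
    g2m_score = binned_control_score(dataset, g2m_present, n_bins, n_ctrl_per_gene, rng)
    return ProliferationResult(
        cell_ids=list(dataset.cell_ids),
        score=np.maximum(s_score, g2m_score),
        s_score=s_score,
        g2m_score=g2m_score,
    )


def split_group(
    dataset: ExpressionDataset, group_label: str, prolif: ProliferationResult
) -> tuple[list[str], list[str]]:
    """Partition a group's cells into proliferative ("p") and non-proliferative
    ("np") lists by the sign of the proliferation score."""
    cells = dataset.cells_of_group(group_label)
    flags = dict(zip(prolif.cell_ids, prolif.is_proliferative))
    p = [c for c in cells if flags[c]]
    np_ = [c for c in cells if not flags[c]]
    return p, np_
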