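"""Transfer of a trained ensemble to a new tissue.

The stored cell-line reference statistics score the tissue cells; the most
confident p21-/p16- low scorers and p21+ or p16+ high scorers anchor a
re-derivation of tissue-specific up/down markers; the marker-set score, with
tissue-internal z-scores, then classifies every tissue cell at the midpoint of
the two anchored group means. The selection size n and the DE log-fold-change
threshold are chosen to maximize the separation of the two anchored score
distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import (
    ConfidentSelection,
    ContractError,
    EnsembleModel,
    ExpressionDataset,
    ProliferationResult,
)
from .classify import gating_counts, select_confident
from .ensemble import wilcoxon_de
from .scoring import score_cells

log = logging.getLogger(__name__)

DEFAULT_N_GRID = (50, 100, 150, 200)
DEFAULT_LOGFC_GRID = (0.25, 0.5, 1.0)


def transfer_scores(tissue_dataset: ExpressionDataset, model: EnsembleModel) -> np.ndarray:
    """EGS scores of tissue cells under the model's stored reference statistics.

    Requires at least ``model.params.min_coverage`` of the model's genes to be
    present in the tissue panel.
    """
    model_genes = {g for p in model.pairs for g in p.genes}
    present = sum(tissue_dataset.has_gene(g) for g in model_genes)
    coverage = present / len(model_genes)
    if coverage < model.params.min_coverage:
        raise ContractError(
            f"only {coverage:.1%} of model genes present in tissue panel "
            f"(floor {model.params.min_coverage:.0%})"
        )
    if coverage < 1.0:
        log.warning("tissue panel covers %.1f%% of model genes", 100 * coverage)
    return score_cells(tissue_dataset, model).egs


def derive_tissue_markers(
    tissue_dataset: ExpressionDataset,
    selection: ConfidentSelection,
    logfc_threshold: float = 0.25,
    adj_p_max: float = 0.05,
    min_expr_frac: float = 0.9,
) -> tuple[list[str], list[str]]:
    """Tissue up/down senescence markers from the confident high vs low cells.

    Wilcoxon DE of high_cells vs low_cells, retaining only genes detected
    (nonzero count) in at least ``min_expr_frac`` of the cells of one of the
    two groups.
    """
    de = wilcoxon_de(
        tissue_dataset, selection.high_cells, selection.low_cells,
        logfc_threshold=logfc_threshold, adj_p_max=adj_p_max,
    )
    hi = tissue_dataset.cell_indices(selection.high_cells)
    lo = tissue_dataset.cell_indices(selection.low_cells)
    up, down = [], []
    for r in de:
        g = tissue_dataset.gene_index(r.gene)
        frac_hi = (tissue_dataset.counts[g, hi] > 0).mean()
        frac_lo = (tissue_dataset.counts[g, lo] > 0).mean()
        if max(frac_hi, frac_lo) >= min_expr_frac:
            (up if r.direction == "up" else down).append(r.gene)
    if not (up or down):
        raise ContractError(
            "no tissue marker passed the filters; try a smaller logfc_threshold"
        )
    return sorted(up), sorted(down)


def tissue_set_score(
    tissue_dataset: ExpressionDataset,
    tissue_up: Sequence[str],
    tissue_down: Sequence[str],
) -> np.ndarray:
    """Mean tissue-internal z of up markers minus mean z of down markers.

    Unlike transfer scoring, the z here uses the tissue's own per-gene mean/SD
    (over all tissue cells): the marker set defines a new score native to the
    tissue.
    """
    if not (list(tissue_up) or list(tissue_down)):
        raise ContractError("marker sets are empty")
    X = tissue_dataset.require_lognorm()
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    safe = np.where(sd == 0, 1.0, sd)

    def side(genes):
        idx = [tissue_dataset.gene_index(g) for g in genes if tissue_dataset.has_gene(g)]
        if not idx:
            return np.zeros(tissue_dataset.n_cells)
        z = (X[idx] - mean[idx, None]) / safe[idx, None]
        z[sd[idx] == 0] = 0.0
        return z.mean(axis=0)

    return side(tissue_up) - side(tissue_down)


@dataclass
class TransferResult:
    tissue_scores: np.ndarray
    selection: ConfidentSelection
    tissue_up: list[str]
    tissue_down: list[str]
    opt_n: int
    opt_logfc: float
    separation: float
    midpoint_threshold: float
    labels: np.ndarray  # boolean senescent per cell
    grid: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "opt_n": self.opt_n,
            "opt_logfc": self.opt_logfc,
            "separation": self.separation,
            "midpoint_threshold": self.midpoint_threshold,
            "tissue_up": self.tissue_up,
            "tissue_down": self.tissue_down,
            "n_senescent": int(self.labels.sum()),
            "n_cells": int(self.labels.size),
            "grid": self.grid,
        }


def separation_statistic(low_scores: np.ndarray, high_scores: np.ndarray) -> float:
    """Pooled-SD standardized mean difference between the two anchored groups."""
    pooled = np.sqrt((high_scores.var(ddof=1) + low_scores.var(ddof=1)) / 2)
    if pooled == 0:
        return float("inf")
    return float((high_scores.mean() - low_scores.mean()) / pooled)


def optimize_transfer(
    tissue_dataset: ExpressionDataset,
    model: EnsembleModel,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    logfc_grid: Sequence[float] = DEFAULT_LOGFC_GRID,
    min_expr_frac: float = 0.9,
    objective: str = "population",
) -> TransferResult:
    """Grid-search (n, logfc_threshold) for the most distinct tissue score
    distributions, then classify all tissue cells at the midpoint threshold.

    For each configuration the anchored groups define the marker sets and the
    midpoint; ``objective`` measures distinctness either between the two
    midpoint-classified cell populations ("population", default) or between
    the anchored groups themselves ("anchors"). The population objective
    penalizes marker sets that separate the anchors but generalize poorly to
    mid-range cells. Ties go to the larger n, then the smaller logfc.
    """
    if not (list(n_grid) and list(logfc_grid)):
        raise ContractError("grids must be nonempty")
    if objective not in ("population", "anchors"):
        raise ContractError(f"unknown objective {objective!r}")
    scores = transfer_scores(tissue_dataset, model)
    p21, p16 = gating_counts(tissue_dataset)
    best = None
    grid_log = []
    for n in sorted(n_grid):
        selection = select_confident(scores, tissue_dataset.cell_ids, p21, p16, n)
        lo_idx = tissue_dataset.cell_indices(selection.low_cells)
        hi_idx = tissue_dataset.cell_indices(selection.high_cells)
        for logfc in sorted(logfc_grid):
            try:
                up, down = derive_tissue_markers(
                    tissue_dataset, selection, logfc_threshold=logfc,
                    min_expr_frac=min_expr_frac,
                )
            except ContractError as e:
                grid_log.append({"n": n, "logfc": logfc, "separation": None,
                                 "reason": str(e)})
                continue
            tscore = tissue_set_score(tissue_dataset, up, down)
            midpoint = float((tscore[lo_idx].mean() + tscore[hi_idx].mean()) / 2)
            pred = tscore > midpoint
            if objective == "population":
                if pred.sum() < 2 or (~pred).sum() < 2:
                    grid_log.append({"n": n, "logfc": logfc, "separation": None,
                                     "reason": "degenerate classification"})
                    continue
                sep = separation_statistic(tscore[~pred], tscore[pred])
            else:
                sep = separation_statistic(tscore[lo_idx], tscore[hi_idx])
            grid_log.append({"n": n, "logfc": logfc, "separation": sep,
                             "n_up": len(up), "n_down": len(down)})
            key = (sep, n, -logfc)
            if best is None or key > best[0]:
                best = (key, n, logfc, selection, up, down, tscore, midpoint)
    if best is None:
        raise ContractError("every grid configuration failed to produce markers")
    key, n, logfc, selection, up, down, tscore, midpoint = best
    return TransferResult(
        tissue_scores=scores,
        selection=selection,
        tissue_up=up,
        tissue_down=down,
        opt_n=n,
        opt_logfc=logfc,
        separation=float(key[0]),
        midpoint_threshold=midpoint,
        labels=tscore > midpoint,
        grid=grid_log,
    )


def top_percent_size(n_cells: int, fraction: float = 0.01) -> int:
    """Round-half-up size of a top-fraction selection (1% of 11,889 cells = 119)."""
    return int(np.floor(n_cells * fraction + 0.5))


@dataclass
class ProliferationAudit:
    n_predicted_senescent: int
    n_proliferative_in_predicted: int
    top_size: int
    n_proliferative_in_top: int

    def to_dict(self) -> dict:
        return vars(self)


def audit_proliferation(
    tissue_dataset: ExpressionDataset,
    labels: Sequence[bool],
    prolif: ProliferationResult,
    scores: Sequence[float],
    top_fraction: float = 0.01,
) -> ProliferationAudit:
    """Count proliferative cells among predicted-senescent cells and among the
    top-fraction scorers (senescent cells are arrested, so both counts should
    be near zero)."""
    labels = np.asarray(labels, dtype=bool)
    flags = dict(zip(prolif.cell_ids, prolif.is_proliferative))
    is_prolif = np.array([flags[c] for c in tissue_dataset.cell_ids])
    if labels.size != is_prolif.size:
        raise ContractError("labels and proliferation results must align")
    top_size = top_percent_size(tissue_dataset.n_cells, top_fraction)
    scores = np.asarray(scores, dtype=float)
    top_idx = np.argsort(scores, kind="stable")[-top_size:]
    n_top_prolif = int(is_prolif[top_idx].sum())
    return ProliferationAudit(
        n_predicted_senescent=int(labels.sum()),
        n_proliferative_in_predicted=int(is_prolif[labels].sum()),
        top_size=top_size,
        n_proliferative_in_top=n_top_prolif,
    )
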