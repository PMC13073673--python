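"""Per-pair scores and the signed-extremum ensemble aggregation.

A pair scores a cell as (mean z of the pair's upregulated genes) minus
(mean z of its downregulated genes). A cell's ensemble (EGS) score is the
element of its pair-score vector with the largest absolute value, sign
preserved — the ensemble reports the single strongest explanation, positive
or negative, rather than an average over all pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ContractError,
    EnsembleModel,
    ExpressionDataset,
    GeneSetPair,
    ScoreVector,
)
from .preprocess import ZMatrix, binned_control_score, zscore_matrix

log = logging.getLogger(__name__)


def pair_scores(z: ZMatrix, pair: GeneSetPair, min_coverage: float = 0.0) -> np.ndarray | None:
    """Per-cell score of one pair; None when the pair is unusable here.

    Genes absent from the z matrix are dropped; an entirely absent side
    contributes 0. A pair is unusable when both sides are absent or when the
    fraction of its genes present falls below ``min_coverage``.
    """
    up = [g for g in pair.up_genes if z.has_gene(g)]
    down = [g for g in pair.down_genes if z.has_gene(g)]
    n_total = len(pair.up_genes) + len(pair.down_genes)
    coverage = (len(up) + len(down)) / n_total
    if not (up or down):
        log.info("pair %s: no gene present, excluded", pair.label)
        return None
    if coverage < min_coverage:
        log.info("pair %s: coverage %.2f below floor %.2f, excluded",
                 pair.label, coverage, min_coverage)
        return None
    n_cells = z.values.shape[1]
    up_mean = (
        z.values[[z.gene_index(g) for g in up]].mean(axis=0) if up else np.zeros(n_cells)
    )
    down_mean = (
        z.values[[z.gene_index(g) for g in down]].mean(axis=0) if down else np.zeros(n_cells)
    )
    return up_mean - down_mean


def pair_score(z: ZMatrix, cell_id: str, pair: GeneSetPair) -> float:
    """Score of one pair for one cell (scalar convenience over pair_scores)."""
    scores = pair_scores(z, pair)
    if scores is None:
        raise ContractError(f"pair {pair.label} has no gene in this dataset")
    return float(scores[z.cell_ids.index(cell_id)])


def aggregate_scores(per_pair_scores: Sequence[float]) -> float:
    """Signed absolute extremum of a pair-score vector.

    Returns the element of maximal |value| with its sign; on an exact |tie|
    between a positive and a negative element the positive one wins.
    """
    v = np.asarray(per_pair_scores, dtype=float)
    if v.size == 0:
        raise ContractError("cannot aggregate an empty score vector")
    amax = np.abs(v).max()
    candidates = v[np.abs(v) == amax]
    return float(candidates.max())


@dataclass
class CellScores:
    """Scores of all cells of a dataset under one ensemble model."""

    cell_ids: list[str]
    pair_labels: list[str]
    per_pair: np.ndarray  # n_pairs x n_cells
    egs: np.ndarray  # n_cells
    argmax_pair: list[str]

    def vectors(self) -> list[ScoreVector]:
        return [
            ScoreVector(cell_id=c, per_pair_scores=self.per_pair[:, i], egs_score=float(self.egs[i]))
            for i, c in enumerate(self.cell_ids)
        ]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "egs_score": self.egs,
                "argmax_pair": self.argmax_pair,
                "n_pairs_used": len(self.pair_labels),
            }
        )


def _aggregate_matrix(per_pair: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-index and value of the signed absolute extremum per column,
    positive winning exact |ties|."""
    absval = np.abs(per_pair)
    amax = absval.max(axis=0)
    # among tied-|max| entries prefer the positive one, then the lowest pair index
    is_cand = absval == amax[None, :]
    keyed = np.where(is_cand, per_pair, -np.inf)
    idx = keyed.argmax(axis=0)
    return idx, per_pair[idx, np.arange(per_pair.shape[1])]


def score_cells(dataset: ExpressionDataset, model: EnsembleModel) -> CellScores:
    """EGS-score every cell of a dataset under a trained model.

    z-scores are computed with the model's stored reference statistics — never
    recomputed from the new data — so scores are comparable across datasets.
    """
    z = zscore_matrix(dataset, model.ref_stats)
    rows: list[np.ndarray] = []
    labels: list[str] = []
    for pair in model.pairs:
        s = pair_scores(z, pair, min_coverage=model.params.min_coverage)
        if s is not None:
            rows.append(s)
            labels.append(pair.label)
    if not rows:
        raise ContractError("no pair of the model is usable on this dataset")
    per_pair = np.vstack(rows)
    idx, egs = _aggregate_matrix(per_pair)
    return CellScores(
        cell_ids=list(dataset.cell_ids),
        pair_labels=labels,
        per_pair=per_pair,
        egs=egs,
        argmax_pair=[labels[i] for i in idx],
    )


def module_score(
    dataset: ExpressionDataset,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl_per_gene: int = 100,
    rng_seed: int = 0,
) -> np.ndarray:
    """Bin-matched module score of a gene set (the classical AddModuleScore-style
    baseline): mean lognorm of the set minus mean lognorm of expression-matched
    random control genes. Seeded and deterministic."""
    rng = np.random.default_rng(rng_seed)
    return binned_control_score(dataset, gene_set, n_bins, n_ctrl_per_gene, rng)
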