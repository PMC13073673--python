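"""Two-Gaussian threshold classification, cross-validation, and the
p21/p16-gated confident-cell selection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats
from sklearn.model_selection import StratifiedKFold

from .datatypes import (
    ClassifierFit,
    ConfidentSelection,
    ContractError,
    EgsParams,
    ExpressionDataset,
)
from .ensemble import build_ensemble
from .scoring import score_cells

log = logging.getLogger(__name__)

P21_GENE = "CDKN1A"
P16_GENE = "CDKN2A"

GRID_POINTS = 2001


def fit_gaussian_threshold(
    scores_ctrl: Sequence[float],
    scores_sen: Sequence[float],
    weighting: str = "counts",
) -> ClassifierFit:
    """Fit a Gaussian to each score sample and pick the threshold minimizing the
    expected number of false positives plus false negatives.

    FP(t) = n_ctrl * (1 - Phi_ctrl(t)) and FN(t) = n_sen * Phi_sen(t) are
    evaluated on a 2001-point grid spanning [mu_ctrl - 3 sd_ctrl,
    mu_sen + 3 sd_sen]; exact ties go to the larger t. ``weighting='equal'``
    drops the group-size weights (equal priors).
    """
    c = np.asarray(scores_ctrl, dtype=float)
    s = np.asarray(scores_sen, dtype=float)
    if c.size < 2 or s.size < 2:
        raise ContractError("need at least 2 scores per class")
    mu_c, sd_c = float(c.mean()), float(c.std(ddof=1))
    mu_s, sd_s = float(s.mean()), float(s.std(ddof=1))
    if sd_c <= 0 or sd_s <= 0:
        raise ContractError("both score samples need positive variance")
    if not mu_s > mu_c:
        raise ContractError("mean senescent score must exceed mean control score "
                            "(labels likely swapped)")
    if weighting == "counts":
        w_c, w_s = c.size, s.size
    elif weighting == "equal":
        w_c = w_s = 1
    else:
        raise ContractError(f"unknown weighting {weighting!r}")
    grid = np.linspace(mu_c - 3 * sd_c, mu_s + 3 * sd_s, GRID_POINTS)
    fp = w_c * scipy.stats.norm.sf(grid, loc=mu_c, scale=sd_c)
    fn = w_s * scipy.stats.norm.cdf(grid, loc=mu_s, scale=sd_s)
    total = fp + fn
    best = np.flatnonzero(total == total.min())[-1]  # ties toward larger t
    return ClassifierFit(
        mu_ctrl=mu_c, sd_ctrl=sd_c, n_ctrl=int(c.size),
        mu_sen=mu_s, sd_sen=sd_s, n_sen=int(s.size),
        threshold=float(grid[best]),
    )


def classify_cells(scores: Sequence[float], threshold: float) -> np.ndarray:
    """Boolean senescent labels: a cell is senescent iff score > threshold (strict)."""
    return np.asarray(scores, dtype=float) > threshold


def select_confident(
    scores: Sequence[float],
    cell_ids: Sequence[str],
    p21_counts: Sequence[float],
    p16_counts: Sequence[float],
    n: int,
) -> ConfidentSelection:
    """The n lowest-score p21-/p16- cells and n highest-score p21+ or p16+ cells.

    Positivity means a nonzero raw transcript count. Score ties are broken by
    cell index, so the selection is independent of input cell order only up to
    identical (score, cell) pairs.
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    scores = np.asarray(scores, dtype=float)
    p21 = np.asarray(p21_counts, dtype=float) > 0
    p16 = np.asarray(p16_counts, dtype=float) > 0
    cell_ids = list(cell_ids)
    if not (scores.size == p21.size == p16.size == len(cell_ids)):
        raise ContractError("scores, counts and cell_ids must align")

    order = sorted(range(scores.size), key=lambda i: (scores[i], cell_ids[i]))
    neg = [i for i in order if not (p21[i] or p16[i])]
    pos = [i for i in order if p21[i] or p16[i]]
    if len(neg) < n:
        raise ContractError(
            f"p21-/p16- stratum has only {len(neg)} cells, need {n}")
    if len(pos) < n:
        raise ContractError(
            f"p21+ or p16+ stratum has only {len(pos)} cells, need {n}")
    return ConfidentSelection(
        low_cells=[cell_ids[i] for i in neg[:n]],
        high_cells=[cell_ids[i] for i in pos[-n:]],
        n=n,
    )


@dataclass
class FoldResult:
    fold: int
    n_test: int
    n_pairs: int
    threshold: float
    accuracy: float
    extremes_accuracy: float
    degenerate: bool = False
    reason: str = ""


@dataclass
class CvReport:
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        ok = [f.accuracy for f in self.folds if not f.degenerate]
        return float(np.mean(ok)) if ok else float("nan")

    @property
    def mean_extremes_accuracy(self) -> float:
        ok = [f.extremes_accuracy for f in self.folds if not f.degenerate]
        return float(np.mean(ok)) if ok else float("nan")

    def to_dict(self) -> dict:
        return {
            "folds": [vars(f) for f in self.folds],
            "mean_accuracy": self.mean_accuracy,
            "mean_extremes_accuracy": self.mean_extremes_accuracy,
        }


def kfold_cv(
    dataset: ExpressionDataset,
    genes_of_interest: Sequence[str],
    control_group: str,
    params: EgsParams,
    sasp_genes: Sequence[str] | None = None,
) -> CvReport:
    """Seeded stratified k-fold cross-validation of the whole scoring pipeline.

    Per fold: the ensemble (including reference statistics) is rebuilt from
    training cells only, test cells are scored and thresholded with a fit on the
    training scores, and accuracy against the group-derived labels is reported
    both overall and restricted to the ``n_confident`` lowest- and
    highest-scoring test cells.
    """
    if params.k_folds < 2:
        raise ContractError("k_folds must be >= 2")
    groups = np.asarray(dataset.cell_meta["group_label"])
    cells = np.asarray(dataset.cell_ids)
    senescent_truth = groups != control_group
    skf = StratifiedKFold(
        n_splits=params.k_folds, shuffle=True, random_state=params.rng_seed
    )
    report = CvReport()
    sen_groups = sorted(set(groups) - {control_group})
    for fold, (train_idx, test_idx) in enumerate(skf.split(cells, groups)):
        train = dataset.subset_cells(cells[train_idx].tolist())
        test = dataset.subset_cells(cells[test_idx].tolist())
        try:
            model = build_ensemble(
                train, genes_of_interest, sen_groups, control_group, params,
                sasp_genes=sasp_genes,
            )
            train_scores = score_cells(train, model)
            train_sen = np.asarray(train.cell_meta["group_label"]) != control_group
            fit = fit_gaussian_threshold(
                train_scores.egs[~train_sen], train_scores.egs[train_sen]
            )
        except ContractError as e:
            report.folds.append(FoldResult(
                fold=fold, n_test=test.n_cells, n_pairs=0, threshold=float("nan"),
                accuracy=float("nan"), extremes_accuracy=float("nan"),
                degenerate=True, reason=str(e),
            ))
            continue
        test_scores = score_cells(test, model)
        pred = classify_cells(test_scores.egs, fit.threshold)
        truth = senescent_truth[test_idx]
        accuracy = float((pred == truth).mean())

        n = min(params.n_confident, test.n_cells // 2)
        order = np.argsort(test_scores.egs, kind="stable")
        extreme = np.concatenate([order[:n], order[-n:]])
        extremes_accuracy = float((pred[extreme] == truth[extreme]).mean())
        report.folds.append(FoldResult(
            fold=fold, n_test=test.n_cells, n_pairs=len(model.pairs),
            threshold=fit.threshold, accuracy=accuracy,
            extremes_accuracy=extremes_accuracy,
        ))
    return report


def gating_counts(dataset: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    """Raw p21 (CDKN1A) and p16 (CDKN2A) counts per cell, for gating."""
    out = []
    for gene in (P21_GENE, P16_GENE):
        if dataset.has_gene(gene):
            out.append(np.asarray(
                dataset.counts[dataset.gene_index(gene)].todense()
            ).ravel())
        else:
            raise ContractError(f"gating gene {gene} absent from dataset")
    return out[0], out[1]
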