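"""Construction of the ensemble of driver-conditioned up/down gene-set pairs.

For every gene of interest and every senescent group, the cells of that group
with z > z_high for the gene ("high expressers") are compared against the
control cells by a per-gene two-sided Wilcoxon rank-sum test; the significant
up- and downregulated genes form one GeneSetPair. One auxiliary "lowSASP" pair
per group is built from cells with absent or low SASP expression, capturing
senescence without a secretory phenotype.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    LOWSASP_TAG,
    ContractError,
    EgsParams,
    EnsembleModel,
    ExpressionDataset,
    GeneSetPair,
)
from .preprocess import ZMatrix, compute_reference_stats, zscore_matrix

log = logging.getLogger(__name__)

_LOG2FC_EPS = 1e-9
_EXACT_MAX_N = 10

# cell-cycle-arrest genes of the interest list: not secreted SASP factors, so
# they do not count toward "low SASP expression" when selecting lowSASP cells
ARREST_GENES = ("CDKN1A", "CDKN2A", "TP53")


@dataclass
class DeResult:
    """One differentially expressed gene from a two-group comparison."""

    gene: str
    log2fc: float
    p_value: float
    adj_p: float
    direction: str  # "up" or "down"


def select_high_expressers(
    z: ZMatrix, driver_gene: str, z_high: float
) -> tuple[list[str], Optional[str]]:
    """Cells with z[driver] strictly above z_high, in stable cell order.

    Returns (cell_ids, reason); reason is non-None when the driver is absent
    from the reference or has zero reference SD, in which case the list is empty.
    """
    driver_gene = driver_gene.upper()
    if not z.has_gene(driver_gene):
        return [], f"driver {driver_gene} absent from reference-covered genes"
    if not z.is_usable_driver(driver_gene):
        return [], f"driver {driver_gene} has zero reference SD"
    mask = z.row(driver_gene) > z_high
    return [c for c, m in zip(z.cell_ids, mask) if m], None


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration (tie-aware mid-ranks).

    Two-sided p is twice the smaller tail probability of the observed rank sum,
    capped at 1; each tail includes the observed value.
    """
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n, nx = pooled.size, x.size
    w_obs = ranks[:nx].sum()
    n_le = n_ge = 0
    for combo in itertools.combinations(range(n), nx):
        w = ranks[list(combo)].sum()
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    total = comb(n, nx)
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def wilcoxon_de(
    dataset: ExpressionDataset,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    logfc_threshold: float = 0.25,
    adj_p_max: float = 0.05,
) -> list[DeResult]:
    """Per-gene two-sided Wilcoxon rank-sum DE of group a vs group b on lognorm.

    log2FC is computed on de-logged means with pseudocount 1e-9; genes with
    |log2FC| below ``logfc_threshold`` are skipped before testing; p-values are
    Bonferroni-adjusted over the tested genes and results with adjusted
    p <= ``adj_p_max`` are returned, ordered by (adj_p, gene).

    Group sizes of at most 10 on both sides use exact enumeration; larger
    groups use the tie- and continuity-corrected normal approximation.
    """
    ia = dataset.cell_indices(cells_a)
    ib = dataset.cell_indices(cells_b)
    if set(ia.tolist()) & set(ib.tolist()):
        raise ContractError("cells_a and cells_b must be disjoint")
    if ia.size < 3 or ib.size < 3:
        raise ContractError("both groups need at least 3 cells")
    X = dataset.require_lognorm()
    A, B = X[:, ia], X[:, ib]

    mean_a = np.expm1(A).mean(axis=1)
    mean_b = np.expm1(B).mean(axis=1)
    log2fc = np.log2((mean_a + _LOG2FC_EPS) / (mean_b + _LOG2FC_EPS))
    tested = np.flatnonzero(np.abs(log2fc) >= logfc_threshold)
    if tested.size == 0:
        return []

    if ia.size <= _EXACT_MAX_N and ib.size <= _EXACT_MAX_N:
        pvals = np.array([_exact_ranksum_p(A[g], B[g]) for g in tested])
    else:
        res = scipy.stats.mannwhitneyu(
            A[tested], B[tested], axis=1, alternative="two-sided",
            method="asymptotic", use_continuity=True,
        )
        pvals = np.atleast_1d(res.pvalue)

    adj = multipletests(pvals, method="bonferroni")[1]
    out = [
        DeResult(
            gene=dataset.gene_ids[g],
            log2fc=float(log2fc[g]),
            p_value=float(p),
            adj_p=float(q),
            direction="up" if log2fc[g] > 0 else "down",
        )
        for g, p, q in zip(tested, pvals, adj)
        if q <= adj_p_max
    ]
    out.sort(key=lambda r: (r.adj_p, r.gene))
    return out


def _pair_from_de(
    de: list[DeResult], driver: str, group: str, n_driver_cells: int
) -> Optional[GeneSetPair]:
    up = [r.gene for r in de if r.direction == "up"]
    down = [r.gene for r in de if r.direction == "down"]
    if not (up or down):
        log.info("pair %s@%s: no significant genes, skipped", driver, group)
        return None
    return GeneSetPair(
        driver=driver, group=group, up_genes=up, down_genes=down,
        n_driver_cells=n_driver_cells,
    )


def build_gene_set_pair(
    dataset: ExpressionDataset,
    z: ZMatrix,
    driver_gene: str,
    group_label: str,
    control_cells: Sequence[str],
    params: EgsParams,
) -> Optional[GeneSetPair]:
    """Build the up/down pair for one driver in one group, or None.

    High expressers of the driver within the group are compared against the
    control cells; fewer than ``params.min_cells`` high expressers vetoes the
    pair (logged).
    """
    driver_gene = driver_gene.upper()
    high, reason = select_high_expressers(z, driver_gene, params.z_high)
    if reason is not None:
        log.info("pair %s@%s skipped: %s", driver_gene, group_label, reason)
        return None
    group_cells = set(dataset.cells_of_group(group_label))
    high_in_group = [c for c in high if c in group_cells]
    if len(high_in_group) < params.min_cells:
        log.info(
            "pair %s@%s skipped: %d high-expresser cells < min_cells %d",
            driver_gene, group_label, len(high_in_group), params.min_cells,
        )
        return None
    de = wilcoxon_de(
        dataset, high_in_group, control_cells,
        logfc_threshold=params.logfc_threshold, adj_p_max=params.adj_p_max,
    )
    return _pair_from_de(de, driver_gene, group_label, len(high_in_group))


def select_lowsasp_cells(
    dataset: ExpressionDataset,
    z: ZMatrix,
    sasp_genes: Sequence[str],
    group_label: str,
    params: EgsParams,
) -> list[str]:
    """Cells of a group with absent/low SASP expression: bottom-quartile fraction
    of SASP genes detected AND no SASP gene above the high-expresser z cutoff."""
    sasp = sorted({g.upper() for g in sasp_genes if dataset.has_gene(g)})
    if not sasp:
        raise ContractError("no SASP gene present in dataset")
    cells = dataset.cells_of_group(group_label)
    idx = dataset.cell_indices(cells)
    gidx = np.array([dataset.gene_index(g) for g in sasp])
    nonzero_frac = np.asarray(
        (dataset.counts[gidx][:, idx] > 0).mean(axis=0)
    ).ravel()
    cutoff = np.quantile(nonzero_frac, params.lowsasp_quantile)
    z_usable = [g for g in sasp if z.is_usable_driver(g)]
    if z_usable:
        zrows = np.array([z.gene_index(g) for g in z_usable])
        cell_pos = {c: i for i, c in enumerate(z.cell_ids)}
        zcols = np.array([cell_pos[c] for c in cells])
        max_z = z.values[np.ix_(zrows, zcols)].max(axis=0)
    else:
        max_z = np.zeros(len(cells))
    keep = (nonzero_frac <= cutoff) & (max_z <= params.z_high)
    return [c for c, k in zip(cells, keep) if k]


def build_lowsasp_pair(
    dataset: ExpressionDataset,
    z: ZMatrix,
    sasp_genes: Sequence[str],
    group_label: str,
    control_cells: Sequence[str],
    params: EgsParams,
) -> Optional[GeneSetPair]:
    """Auxiliary pair from SASP-silent cells of a group, tagged driver='lowSASP'."""
    low_cells = select_lowsasp_cells(dataset, z, sasp_genes, group_label, params)
    if len(low_cells) < params.min_cells:
        log.info(
            "lowSASP@%s skipped: %d cells < min_cells %d",
            group_label, len(low_cells), params.min_cells,
        )
        return None
    de = wilcoxon_de(
        dataset, low_cells, control_cells,
        logfc_threshold=params.logfc_threshold, adj_p_max=params.adj_p_max,
    )
    return _pair_from_de(de, LOWSASP_TAG, group_label, len(low_cells))


def build_ensemble(
    dataset: ExpressionDataset,
    genes_of_interest: Sequence[str],
    groups: Sequence[str],
    control_group: str,
    params: EgsParams,
    sasp_genes: Optional[Sequence[str]] = None,
) -> EnsembleModel:
    """Build the full ensemble over genes_of_interest x groups plus one lowSASP
    attempt per group, with reference stats frozen from the control group.

    Deterministic given inputs; raises if no pair at all can be built.
    """
    if sasp_genes is None:
        sasp_genes = [g for g in genes_of_interest if g.upper() not in ARREST_GENES]
    control_cells = dataset.cells_of_group(control_group)
    ref_stats = compute_reference_stats(dataset, control_cells)
    z = zscore_matrix(dataset, ref_stats)
    pairs: list[GeneSetPair] = []
    for group in groups:
        for gene in sorted({g.upper() for g in genes_of_interest}):
            pair = build_gene_set_pair(dataset, z, gene, group, control_cells, params)
            if pair is not None:
                pairs.append(pair)
        low = build_lowsasp_pair(dataset, z, sasp_genes, group, control_cells, params)
        if low is not None:
            pairs.append(low)
    if not pairs:
        raise ContractError("no gene-set pair could be built; ensemble unusable")
    return EnsembleModel(pairs=pairs, ref_stats=ref_stats, params=params)
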