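#!/usr/bin/env python
"""Transfer the cell-line ensemble to a simulated tissue cohort: score under
stored reference statistics, anchor confident normal/senescent cells with
p21/p16 gating, re-derive tissue markers over the (n, logfc) grid, classify at
the midpoint threshold, and audit the proliferation status of top scorers.

Writes results/04_transfer_summary.tsv and results/04_tissue_markers.gmt.
"""

import os
import sys

import numpy as np
import pandas as pd

import senescore as ss
from senescore.simulate import design_universe

SEED = 0
TISSUE_SEED = 1


def main() -> None:
    os.makedirs("results", exist_ok=True)
    ref_config = ss.default_config(SEED)
    dataset, _ = ss.simulate(ref_config)
    dataset = ss.lognormalize(dataset)
    goi = ss.load_genes_of_interest()
    groups = sorted(set(dataset.cell_meta["group_label"]) - {"PDL_25p"})
    model = ss.build_ensemble(dataset, goi, groups, "PDL_25p", ss.EgsParams())

    universe = design_universe(ref_config, np.random.default_rng(SEED))
    tissue, truth = ss.simulate(ss.tissue_config(TISSUE_SEED), universe=universe)
    tissue = ss.lognormalize(tissue)

    result = ss.optimize_transfer(tissue, model)
    s_genes, g2m_genes = ss.load_cell_cycle_genes()
    prolif = ss.proliferation_score(tissue, s_genes, g2m_genes, rng_seed=SEED)
    audit = ss.audit_proliferation(
        tissue, result.labels, prolif, result.tissue_scores
    )
    sen = truth.senescent_mask
    balanced = (result.labels[sen].mean() + (1 - result.labels[~sen]).mean()) / 2

    summary = pd.DataFrame([{
        "opt_n": result.opt_n,
        "opt_logfc": result.opt_logfc,
        "separation": round(result.separation, 3),
        "midpoint_threshold": round(result.midpoint_threshold, 4),
        "n_up_markers": len(result.tissue_up),
        "n_down_markers": len(result.tissue_down),
        "n_predicted_senescent": int(result.labels.sum()),
        "n_cells": tissue.n_cells,
        "balanced_accuracy": round(float(balanced), 4),
        "top1pct_size": audit.top_size,
        "proliferative_in_top1pct": audit.n_proliferative_in_top,
        "proliferative_in_predicted": audit.n_proliferative_in_predicted,
    }])
    summary.to_csv("results/04_transfer_summary.tsv", sep="\t", index=False)
    ss.write_gmt(
        [("TISSUE_UP", result.tissue_up), ("TISSUE_DOWN", result.tissue_down)],
        "results/04_tissue_markers.gmt",
        description="derived tissue senescence markers",
    )
    print(summary.T.to_string(header=False))


if __name__ == "__main__":
    sys.exit(main())
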