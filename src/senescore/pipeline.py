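"""End-to-end orchestration of the reference and tissue-transfer workflows.

Each workflow writes its artifacts plus a JSON run manifest (seed, parameters,
stage list) sufficient to regenerate them. A single global seed is fanned out
to per-stage child seeds through :class:`numpy.random.SeedSequence` so stages
stay individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .datatypes import ContractError, EgsParams, EnsembleModel, ExpressionDataset
from .classify import fit_gaussian_threshold, kfold_cv
from .ensemble import build_ensemble
from .io import (
    load_cell_cycle_genes,
    load_genes_of_interest,
    read_matrix_market,
    write_gmt,
    write_scores_tsv,
)
from .preprocess import lognormalize, proliferation_score
from .scoring import score_cells
from .simulate import SimConfig, simulate
from .transfer import audit_proliferation, optimize_transfer

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    out_dir: str
    counts_dir: Optional[str] = None
    meta_path: Optional[str] = None
    control_group: str = "PDL_25p"
    genes_of_interest: Optional[Sequence[str]] = None
    params: EgsParams = field(default_factory=EgsParams)
    sim: Optional[SimConfig] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "params" in raw:
            raw["params"] = EgsParams.from_dict(raw["params"])
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "groups" in sim:
                sim["groups"] = [tuple(g) for g in sim["groups"]]
            raw["sim"] = SimConfig(**sim)
        return cls(**raw)

    def to_manifest_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        # normalize to JSON-stable types (tuples become lists)
        return json.loads(json.dumps(d))


def child_seeds(seed: int, n: int) -> list[int]:
    """Fan a global seed out into per-stage child seeds (each below 2**31)."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def _load_dataset(config: PipelineConfig) -> ExpressionDataset:
    if config.sim is not None:
        dataset, _ = simulate(config.sim)
        return dataset
    if config.counts_dir is None:
        raise ContractError("config needs either a sim block or a counts_dir")
    return read_matrix_market(config.counts_dir, meta_path=config.meta_path)


def _write_manifest(config: PipelineConfig, stages: list[str], path: str) -> None:
    manifest = {
        "senescore_version": __version__,
        "seed": config.seed,
        "stages": stages,
        "config": config.to_manifest_dict(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_reference_workflow(config: PipelineConfig) -> dict:
    """preprocess -> build_ensemble -> score -> fit threshold -> cross-validate.

    Returns the in-memory artifacts and writes model.json, scores.tsv,
    fit.json, cv.json and manifest.json under ``config.out_dir``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    stages = []
    goi = (list(config.genes_of_interest) if config.genes_of_interest is not None
           else load_genes_of_interest())

    dataset = _load_dataset(config)
    params = dataclasses.replace(config.params, rng_seed=config.seed)

    dataset = lognormalize(dataset, params.scale_factor)
    stages.append("preprocess")

    groups = sorted(set(dataset.cell_meta["group_label"]) - {config.control_group})
    model = build_ensemble(dataset, goi, groups, config.control_group, params)
    model.to_json(os.path.join(config.out_dir, "model.json"))
    stages.append("build_ensemble")

    scores = score_cells(dataset, model)
    sen = np.asarray(dataset.cell_meta["group_label"]) != config.control_group
    fit = fit_gaussian_threshold(scores.egs[~sen], scores.egs[sen])
    labels = ["senescent" if s > fit.threshold else "normal" for s in scores.egs]
    write_scores_tsv(dataset.cell_ids, scores.egs, labels,
                     os.path.join(config.out_dir, "scores.tsv"))
    stages.append("score")
    with open(os.path.join(config.out_dir, "fit.json"), "w") as fh:
        json.dump(fit.to_dict(), fh, indent=1)
    stages.append("fit_threshold")

    cv = kfold_cv(dataset, goi, config.control_group, params)
    with open(os.path.join(config.out_dir, "cv.json"), "w") as fh:
        json.dump(cv.to_dict(), fh, indent=1)
    stages.append("cross_validate")

    _write_manifest(config, stages, os.path.join(config.out_dir, "manifest.json"))
    return {"dataset": dataset, "model": model, "scores": scores, "fit": fit, "cv": cv}


def run_transfer_workflow(
    config: PipelineConfig,
    model_path: str,
    tissue_dataset: Optional[ExpressionDataset] = None,
) -> dict:
    """transfer -> select/optimize -> classify -> proliferation audit.

    ``tissue_dataset`` overrides loading from config paths (used when the
    tissue cohort was simulated in-process).
    """
    if not os.path.exists(model_path):
        raise ContractError(f"model artifact not found: {model_path}")
    os.makedirs(config.out_dir, exist_ok=True)
    stages = []
    model = EnsembleModel.from_json(model_path)
    if tissue_dataset is None:
        tissue_dataset = _load_dataset(config)
    if tissue_dataset.lognorm is None:
        tissue_dataset = lognormalize(tissue_dataset, model.params.scale_factor)
    stages.append("preprocess")

    result = optimize_transfer(tissue_dataset, model)
    stages.append("optimize_transfer")

    s_genes, g2m_genes = load_cell_cycle_genes()
    prolif = proliferation_score(
        tissue_dataset, s_genes, g2m_genes, rng_seed=child_seeds(config.seed, 1)[0]
    )
    audit = audit_proliferation(
        tissue_dataset, result.labels, prolif, result.tissue_scores
    )
    stages.append("audit_proliferation")

    with open(os.path.join(config.out_dir, "transfer.json"), "w") as fh:
        json.dump({**result.to_dict(), "audit": audit.to_dict()}, fh, indent=1)
    write_gmt(
        [("TISSUE_UP", result.tissue_up), ("TISSUE_DOWN", result.tissue_down)],
        os.path.join(config.out_dir, "tissue_markers.gmt"),
        description="derived tissue senescence markers",
    )
    write_scores_tsv(
        tissue_dataset.cell_ids,
        result.tissue_scores,
        ["senescent" if l else "normal" for l in result.labels],
        os.path.join(config.out_dir, "tissue_labels.tsv"),
    )
    _write_manifest(config, stages, os.path.join(config.out_dir, "transfer_manifest.json"))
    return {"tissue": tissue_dataset, "result": result, "audit": audit, "model": model}
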