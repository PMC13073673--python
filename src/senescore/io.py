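"""Readers and writers for the standard formats the pipeline touches.

Matrix Market triplets in the 10x dialect (matrix.mtx + features.tsv +
barcodes.tsv), GMT gene sets, and TSV score tables. Matrix parsing is
delegated to :func:`scipy.io.mmread` / :func:`scipy.io.mmwrite`.
"""

from __future__ import annotations

import logging
import os
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import ContractError, ExpressionDataset, FormatError

log = logging.getLogger(__name__)

_MTX_NAMES = ("matrix.mtx", "counts.mtx")
_FEATURE_NAMES = ("features.tsv", "genes.tsv")
_BARCODE_NAMES = ("barcodes.tsv",)


def _find(directory: str, candidates: Sequence[str], what: str) -> str:
    for name in candidates:
        path = os.path.join(directory, name)
        if os.path.exists(path):
            return path
    raise FormatError(f"no {what} file found in {directory!r} (tried {candidates})")


def read_matrix_market(directory_path: str, meta_path: str | None = None) -> ExpressionDataset:
    """Read a 10x-style Matrix Market triplet directory into an ExpressionDataset.

    Duplicate gene symbols (after upper-casing) are collapsed by summation with
    a logged warning. ``meta_path``, when given, points to a TSV with a
    ``cell_id`` column and per-cell annotations such as ``group_label``.
    """
    mtx_path = _find(directory_path, _MTX_NAMES, "Matrix Market")
    feat_path = _find(directory_path, _FEATURE_NAMES, "features")
    bc_path = _find(directory_path, _BARCODE_NAMES, "barcodes")

    counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
    features = pd.read_csv(feat_path, sep="\t", header=None)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)
    genes = features.iloc[:, -1].astype(str).str.upper().tolist() if features.shape[1] == 1 \
        else features.iloc[:, 1].astype(str).str.upper().tolist()
    cells = barcodes.iloc[:, 0].astype(str).tolist()
    if counts.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix is {counts.shape} but features/barcodes give "
            f"({len(genes)}, {len(cells)})"
        )

    if len(set(genes)) != len(genes):
        genes, counts = _collapse_duplicate_genes(genes, counts)

    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("cell_id")
    return ExpressionDataset(gene_ids=genes, cell_ids=cells, counts=counts, cell_meta=meta)


def _collapse_duplicate_genes(genes, counts):
    order = pd.unique(pd.Series(genes))
    dupes = sorted({g for g in order if genes.count(g) > 1})
    log.warning("collapsing %d duplicated gene symbol(s) by summation: %s", len(dupes), dupes)
    pos = {g: i for i, g in enumerate(order)}
    rows = np.array([pos[g] for g in genes])
    indic = sp.csr_matrix(
        (np.ones(len(genes)), (rows, np.arange(len(genes)))), shape=(len(order), len(genes))
    )
    return list(order), sp.csr_matrix(indic @ counts)


def write_matrix_market(dataset: ExpressionDataset, directory_path: str) -> None:
    """Write the counts layer as a 10x-style triplet (plus cell_meta TSV)."""
    os.makedirs(directory_path, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(directory_path, "matrix.mtx"), sp.coo_matrix(dataset.counts), field="integer"
    )
    pd.Series(dataset.gene_ids).to_csv(
        os.path.join(directory_path, "features.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(dataset.cell_ids).to_csv(
        os.path.join(directory_path, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    if len(dataset.cell_meta.columns):
        dataset.cell_meta.to_csv(os.path.join(directory_path, "cell_meta.tsv"), sep="\t")


def read_gmt(path) -> list[tuple[str, list[str]]]:
    """Parse a GMT file into (set name, member genes) tuples.

    Genes are upper-cased; blank lines are skipped; duplicate set names and
    lines with fewer than three fields raise a FormatError.
    """
    out: list[tuple[str, list[str]]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT line needs >=3 fields")
            name = fields[0]
            if name in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            out.append((name, [g.upper() for g in fields[2:] if g]))
    return out


def write_gmt(sets: Sequence[tuple[str, Sequence[str]]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets:
            fh.write("\t".join([name, description, *[g.upper() for g in genes]]) + "\n")


def write_scores_tsv(cell_ids, scores, labels, path) -> None:
    """Write a cell_id / sasp_score / label table (scores at >=6 sig. digits)."""
    cell_ids, scores, labels = list(cell_ids), list(scores), list(labels)
    if not (len(cell_ids) == len(scores) == len(labels)):
        raise ContractError("cell_ids, scores, labels must have equal lengths")
    with open(path, "w") as fh:
        fh.write("cell_id\tsasp_score\tlabel\n")
        for c, s, l in zip(cell_ids, scores, labels):
            fh.write(f"{c}\t{s:.9g}\t{l}\n")


def read_scores_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str, "sasp_score": float, "label": str})


# -- packaged gene-list fixtures ----------------------------------------

def load_cell_cycle_genes() -> tuple[list[str], list[str]]:
    """The packaged S-phase and G2/M signature gene lists."""
    with resources.as_file(resources.files("senescore.data") / "cell_cycle.gmt") as p:
        sets = dict(read_gmt(p))
    return sets["S_PHASE"], sets["G2M_PHASE"]


def load_genes_of_interest() -> list[str]:
    """The packaged 106 SASP factors and senescence genes of interest."""
    with resources.as_file(resources.files("senescore.data") / "genes_of_interest.gmt") as p:
        sets = dict(read_gmt(p))
    return sets["SASP_AND_INTEREST"]
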