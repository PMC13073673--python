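"""Synthetic scRNA-seq generator with planted senescence structure.

The generator emulates the statistical structure the EGS analysis assumes: a
proliferating control group plus early/mature senescent groups. Each senescent
group contains subpopulations with elevated expression of planted driver genes,
each driver coupled to a planted up/down co-expression program; p21 (CDKN1A)
and p16 (CDKN2A) transcripts are present in configured fractions of senescent
cells and near-absent in controls; the packaged S/G2M cell-cycle genes are
elevated only in cycling cells and suppressed in arrested (senescent) cells.

Counts are negative-binomial around per-cell library-size-scaled means; all
planted effects are injected in log-mean space before sampling, so an effect of
1.5 shifts the log-normalized expression of an affected gene by roughly 1.5.
Ground truth for every planted feature is returned alongside the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import ContractError, ExpressionDataset
from .io import load_cell_cycle_genes

CONTROL = "control"
EARLY = "early_senescent"
MATURE = "mature_senescent"
_CLASSES = (CONTROL, EARLY, MATURE)

_DRIVER_SYMBOLS = [
    "IGFBP7", "SERPINE2", "MMP1", "MMP3", "IL6",
    "TIMP1", "CCL2", "IGFBP5", "CXCL12", "HGF",
]

P21 = "CDKN1A"
P16 = "CDKN2A"

# baseline linear mean counts for the structural gene classes; signature and
# program genes are moderately expressed so presence/absence filters downstream
# (>=90%-detected marker rule) behave as they would on real fibroblast data
_BASE_MEAN_DRIVER = 4.0
_BASE_MEAN_PROGRAM = 4.0
_BASE_MEAN_CC = 1.0  # quiescent baseline; kept low so the cycle-gene library
# mass of cycling cells stays a small fraction of the total (composition
# effects on normalized counts then stay below the DE log-fold-change filter)
_BASE_MEAN_MARKER_CTRL = 0.05
_MARKER_ON_MEAN = 3.0


@dataclass
class SimConfig:
    """Study conditions of a simulated cohort.

    groups: (label, n_cells, class) with class one of control /
    early_senescent / mature_senescent. Early senescent groups express the
    planted programs at ``early_effect_scale`` times the full effect.
    """

    n_genes: int = 1500
    groups: Sequence[tuple[str, int, str]] = (
        ("PDL_25p", 900, CONTROL),
        ("PDL_46np", 1000, EARLY),
        ("PDL_50np", 1000, MATURE),
    )
    n_drivers: int = 10
    program_size: int = 20  # up and down genes per driver
    subpop_frac: float = 0.07  # mean fraction; per-driver sizes are jittered
    # 0.5-1.5x so only part of the driver subpopulations clear the min-cell rule
    effect_lognorm: float = 1.5
    nb_dispersion: float = 0.1
    libsize_lognormal_params: tuple[float, float] = (0.0, 0.3)
    p21_frac_senescent: float = 0.8
    p16_frac_senescent: float = 0.3
    cc_active_in_control: bool = True
    seed: int = 0
    # secondary knobs
    n_core_drivers: int = 0  # first k drivers planted in every senescent cell
    early_effect_scale: float = 0.7
    cycling_frac_control: float = 1.0
    cc_effect: float = 1.2  # cycling cells: cycle genes ~3-fold up
    cc_arrest_shift: float = 3.0  # full G1 arrest: cycle genes ~20-fold down
    cc_quiescent_shift: float = 0.0  # shallow cycle-gene repression in
    # non-cycling control cells (reversible quiescence, lighter than arrest)
    lowsasp_frac: float = 0.15  # senescent cells with silenced SASP drivers
    lowsasp_shift: float = 3.0  # log-mean suppression of drivers in those cells
    allow_overlap: bool = False  # True lets a cell join several driver subpops

    def __post_init__(self) -> None:
        for frac in (self.subpop_frac, self.p21_frac_senescent,
                     self.p16_frac_senescent, self.cycling_frac_control,
                     self.lowsasp_frac):
            if not 0 <= frac <= 1:
                raise ContractError("fractions must be in [0, 1]")
        for label, n, cls in self.groups:
            if cls not in _CLASSES:
                raise ContractError(f"unknown group class {cls!r}")
            if n < 1:
                raise ContractError(f"group {label}: n_cells must be >= 1")
        if self.n_core_drivers > self.n_drivers:
            raise ContractError("n_core_drivers cannot exceed n_drivers")


@dataclass
class GeneUniverse:
    """Fixed gene panel shared between simulated cohorts (reference and tissue)."""

    gene_ids: list[str]
    base_log_mean: np.ndarray
    drivers: list[str]
    programs: dict[str, tuple[list[str], list[str]]]
    s_genes: list[str]
    g2m_genes: list[str]


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    cell_ids: list[str]
    cell_class: list[str]
    cycling: np.ndarray
    subpop_members: dict[str, list[str]]
    driver_programs: dict[str, tuple[list[str], list[str]]]
    arrest_down_genes: list[str] = field(default_factory=list)
    lowsasp_members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def senescent_mask(self) -> np.ndarray:
        return np.array([c != CONTROL for c in self.cell_class])

    def truth_labels(self) -> list[str]:
        return ["senescent" if s else "normal" for s in self.senescent_mask]


def design_universe(config: SimConfig, rng: np.random.Generator) -> GeneUniverse:
    """Lay out the gene panel: drivers, p21/p16, cell-cycle genes, per-driver
    programs, and log-normal baseline means for the filler genes."""
    s_genes, g2m_genes = load_cell_cycle_genes()
    drivers = list(_DRIVER_SYMBOLS[: config.n_drivers])
    drivers += [f"DRV{i:02d}" for i in range(len(drivers), config.n_drivers)]
    programs: dict[str, tuple[list[str], list[str]]] = {}
    prog_genes: list[str] = []
    for d in range(config.n_drivers):
        up = [f"PRG{d:02d}_UP{i:02d}" for i in range(config.program_size)]
        down = [f"PRG{d:02d}_DN{i:02d}" for i in range(config.program_size)]
        programs[drivers[d]] = (up, down)
        prog_genes += up + down

    special = drivers + [P21, P16] + s_genes + g2m_genes + prog_genes
    if len(special) > config.n_genes:
        raise ContractError(
            f"{len(special)} structural genes exceed n_genes={config.n_genes}"
        )
    n_filler = config.n_genes - len(special)
    filler = [f"G{i:04d}" for i in range(n_filler)]
    gene_ids = special + filler

    base = np.empty(config.n_genes)
    base[: len(drivers)] = _BASE_MEAN_DRIVER
    base[len(drivers): len(drivers) + 2] = _BASE_MEAN_MARKER_CTRL
    n_cc = len(s_genes) + len(g2m_genes)
    base[len(drivers) + 2: len(drivers) + 2 + n_cc] = _BASE_MEAN_CC
    base[len(drivers) + 2 + n_cc: len(special)] = _BASE_MEAN_PROGRAM
    base[len(special):] = rng.lognormal(mean=np.log(0.3), sigma=1.2, size=n_filler)
    return GeneUniverse(
        gene_ids=gene_ids,
        base_log_mean=np.log(base),
        drivers=drivers,
        programs=programs,
        s_genes=s_genes,
        g2m_genes=g2m_genes,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    size_param = 1.0 / dispersion
    return rng.negative_binomial(size_param, size_param / (size_param + mu))


def simulate(
    config: SimConfig, universe: Optional[GeneUniverse] = None
) -> tuple[ExpressionDataset, SimTruth]:
    """Simulate one cohort; deterministic given (config, universe).

    Passing the ``universe`` of a previous run makes the new cohort share the
    same gene panel and planted driver programs (the tissue-transfer scenario).
    """
    rng = np.random.default_rng(config.seed)
    if universe is None:
        universe = design_universe(config, rng)
    gidx = {g: i for i, g in enumerate(universe.gene_ids)}
    n_genes = len(universe.gene_ids)
    cc_idx = np.array([gidx[g] for g in universe.s_genes + universe.g2m_genes])

    cell_ids: list[str] = []
    cell_class: list[str] = []
    group_labels: list[str] = []
    cycling_flags: list[np.ndarray] = []
    adjust_blocks: list[np.ndarray] = []
    subpop_members: dict[str, list[str]] = {
        d: [] for d in universe.drivers[: config.n_drivers]
    }
    marker_on: dict[str, list[str]] = {P21: [], P16: []}
    lowsasp_members: dict[str, list[str]] = {}
    driver_rows = np.array([gidx[d] for d in universe.drivers[: config.n_drivers]])

    for label, n_cells, cls in config.groups:
        ids = [f"{label}_c{i:04d}" for i in range(n_cells)]
        cell_ids += ids
        group_labels += [label] * n_cells
        cell_class += [cls] * n_cells
        adj = np.zeros((n_genes, n_cells))
        if cls == CONTROL:
            cyc = (
                rng.random(n_cells) < config.cycling_frac_control
                if config.cc_active_in_control
                else np.zeros(n_cells, dtype=bool)
            )
            # cycling cells have elevated cycle genes; quiescent controls sit
            # at (or shallowly below) baseline — reversible arrest
            adj[np.ix_(cc_idx, np.flatnonzero(cyc))] += config.cc_effect
            adj[np.ix_(cc_idx, np.flatnonzero(~cyc))] -= config.cc_quiescent_shift
        else:
            # senescent cells deeply repress cycle genes (irreversible G1 arrest)
            cyc = np.zeros(n_cells, dtype=bool)
            adj[cc_idx, :] -= config.cc_arrest_shift
            # early senescent cells express driver genes fully but their
            # coupled programs only partially (programs mature over time)
            program_effect = config.effect_lognorm * (
                config.early_effect_scale if cls == EARLY else 1.0
            )
            # SASP-silent senescent cells: all driver genes suppressed, no
            # driver subpopulation recruits them
            n_low = int(round(config.lowsasp_frac * n_cells))
            low = np.sort(rng.choice(n_cells, size=n_low, replace=False))
            if n_low:
                adj[np.ix_(driver_rows, low)] -= config.lowsasp_shift
            lowsasp_members[label] = sorted(ids[i] for i in low)
            low_mask = np.zeros(n_cells, dtype=bool)
            low_mask[low] = True
            taken = low_mask.copy()
            for k, driver in enumerate(universe.drivers[: config.n_drivers]):
                if k < config.n_core_drivers:
                    members = np.flatnonzero(~low_mask)
                else:
                    pool = (np.flatnonzero(~low_mask) if config.allow_overlap
                            else np.flatnonzero(~taken))
                    frac = config.subpop_frac * rng.uniform(0.5, 1.5)
                    size = min(int(round(frac * n_cells)), pool.size)
                    members = np.sort(rng.choice(pool, size=size, replace=False))
                    taken[members] = True
                up, down = universe.programs[driver]
                adj[gidx[driver], members] += config.effect_lognorm
                adj[np.ix_([gidx[g] for g in up], members)] += program_effect
                adj[np.ix_([gidx[g] for g in down], members)] -= program_effect
                subpop_members[driver] += [ids[i] for i in members]
            for gene, frac in ((P21, config.p21_frac_senescent),
                               (P16, config.p16_frac_senescent)):
                on = np.flatnonzero(rng.random(n_cells) < frac)
                marker_on[gene] += [ids[i] for i in on]
        cycling_flags.append(cyc)
        adjust_blocks.append(adj)

    adjust = np.concatenate(adjust_blocks, axis=1)
    cycling = np.concatenate(cycling_flags)
    n_total = len(cell_ids)
    mu_lib, sigma_lib = config.libsize_lognormal_params
    lib = rng.lognormal(mean=mu_lib, sigma=sigma_lib, size=n_total)
    mu = np.exp(universe.base_log_mean[:, None] + adjust) * lib[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion).astype(np.int64)

    # presence/absence gating markers: forced nonzero in the configured senescent
    # fractions, forced zero in the other senescent cells, near-zero in controls
    cell_pos = {c: i for i, c in enumerate(cell_ids)}
    sen_cols = np.array([i for i, c in enumerate(cell_class) if c != CONTROL], dtype=int)
    for gene in (P21, P16):
        row = gidx[gene]
        counts[row, sen_cols] = 0
        on_cols = np.array([cell_pos[c] for c in marker_on[gene]], dtype=int)
        if on_cols.size:
            draws = _nb_draw(rng, np.full(on_cols.size, _MARKER_ON_MEAN),
                             config.nb_dispersion)
            counts[row, on_cols] = np.maximum(draws, 1)

    meta = pd.DataFrame(
        {
            "group_label": group_labels,
            "truth_label": ["normal" if c == CONTROL else "senescent" for c in cell_class],
            "truth_class": cell_class,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    dataset = ExpressionDataset(
        gene_ids=universe.gene_ids, cell_ids=cell_ids,
        counts=sp.csr_matrix(counts), cell_meta=meta,
    )
    truth = SimTruth(
        cell_ids=cell_ids,
        cell_class=cell_class,
        cycling=cycling,
        subpop_members={d: sorted(v) for d, v in subpop_members.items()},
        driver_programs={
            d: universe.programs[d] for d in universe.drivers[: config.n_drivers]
        },
        arrest_down_genes=(
            sorted(universe.s_genes + universe.g2m_genes)
            if config.cc_arrest_shift > 0 else []
        ),
        lowsasp_members=lowsasp_members,
    )
    return dataset, truth


def default_config(seed: int = 0) -> SimConfig:
    return SimConfig(seed=seed)


def tissue_config(seed: int = 1) -> SimConfig:
    """A tissue-like cohort: one fibroblast pool with a 30% senescent fraction,
    three core drivers shared by all senescent cells, sparse cycling normals."""
    return SimConfig(
        groups=(
            ("tissue_normal", 1750, CONTROL),
            ("tissue_senescent", 750, MATURE),
        ),
        n_drivers=3,
        n_core_drivers=3,
        cc_active_in_control=True,
        cycling_frac_control=0.15,
        seed=seed,
    )


_FIXTURES = {
    "tiny-2group": "200 genes x 300 cells, control + mature senescent",
    "wi38-like": "replicative-senescence time course, 4300 cells in 5 PDL groups",
    "tissue-like": "2500 tissue fibroblasts, 30% senescent, shared driver programs",
}


def make_fixture(name: str, seed: int = 0) -> tuple[ExpressionDataset, SimTruth]:
    """Deterministic packaged datasets for tests and docs."""
    if name == "tiny-2group":
        cfg = SimConfig(
            n_genes=200,
            groups=(("ctrl", 150, CONTROL), ("sen", 150, MATURE)),
            n_drivers=3, program_size=5, subpop_frac=0.3,
            seed=seed,
        )
        return simulate(cfg)
    if name == "wi38-like":
        cfg = SimConfig(
            groups=(
                ("PDL_25p", 900, CONTROL),
                ("PDL_29np", 573, EARLY),
                ("PDL_33np", 657, EARLY),
                ("PDL_46np", 1179, MATURE),
                ("PDL_50np", 991, MATURE),
            ),
            seed=seed,
        )
        return simulate(cfg)
    if name == "tissue-like":
        ref_rng = np.random.default_rng(seed)
        universe = design_universe(default_config(seed), ref_rng)
        return simulate(tissue_config(seed + 1), universe=universe)
    raise ContractError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
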