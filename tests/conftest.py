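"""Shared fixtures: one reference cohort + trained model, one tissue cohort.

Everything is generated programmatically with fixed seeds so the suite is
deterministic and ships no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import senescore as ss
from senescore.simulate import design_universe

REF_SEED = 0
TISSUE_SEED = 1
SEN_GROUPS = ["PDL_46np", "PDL_50np"]
CONTROL_GROUP = "PDL_25p"


@pytest.fixture(scope="session")
def ref_data():
    """Default synthetic replicative-senescence cohort, log-normalized."""
    dataset, truth = ss.simulate(ss.default_config(REF_SEED))
    return ss.lognormalize(dataset), truth


@pytest.fixture(scope="session")
def genes_of_interest():
    return ss.load_genes_of_interest()


@pytest.fixture(scope="session")
def ref_model(ref_data, genes_of_interest):
    dataset, _ = ref_data
    return ss.build_ensemble(
        dataset, genes_of_interest, SEN_GROUPS, CONTROL_GROUP, ss.EgsParams()
    )


@pytest.fixture(scope="session")
def ref_scores(ref_data, ref_model):
    dataset, _ = ref_data
    return ss.score_cells(dataset, ref_model)


@pytest.fixture(scope="session")
def tissue_data(ref_data):
    """Tissue cohort sharing the reference cohort's gene panel and programs."""
    universe = design_universe(ss.default_config(REF_SEED), np.random.default_rng(REF_SEED))
    dataset, truth = ss.simulate(ss.tissue_config(TISSUE_SEED), universe=universe)
    return ss.lognormalize(dataset), truth


@pytest.fixture(scope="session")
def transfer_result(tissue_data, ref_model):
    dataset, _ = tissue_data
    return ss.optimize_transfer(dataset, ref_model)


@pytest.fixture(scope="session")
def tissue_prolif(tissue_data):
    dataset, _ = tissue_data
    s_genes, g2m_genes = ss.load_cell_cycle_genes()
    return ss.proliferation_score(dataset, s_genes, g2m_genes, rng_seed=7)
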