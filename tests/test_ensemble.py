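"""Gene-set pair construction: high-expresser selection, Wilcoxon DE against
an exact-permutation oracle, lowSASP selection, and ensemble assembly."""

import itertools
import json
from math import comb

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats

import senescore as ss
from senescore.datatypes import ContractError
from senescore.ensemble import ARREST_GENES, select_lowsasp_cells, wilcoxon_de
from senescore.preprocess import ZMatrix, compute_reference_stats, zscore_matrix


def make_z(gene_ids, values):
    values = np.asarray(values, dtype=float)
    return ZMatrix(
        gene_ids=list(gene_ids),
        cell_ids=[f"c{j}" for j in range(values.shape[1])],
        values=values,
        sd_zero=np.zeros(values.shape[0], dtype=bool),
    )


class TestSelectHighExpressers:
    def test_all_below_cutoff_gives_empty(self):
        z = make_z(["D"], [[1.0, 1.5, -2.0]])
        cells, reason = ss.select_high_expressers(z, "D", 1.5)
        assert cells == [] and reason is None

    def test_strict_inequality_at_boundary(self):
        z = make_z(["D"], [[1.6, 1.5, 2.0]])
        cells, _ = ss.select_high_expressers(z, "D", 1.5)
        assert cells == ["c0", "c2"]

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(1, 200))
        z = make_z(["D"], vals)
        cells, _ = ss.select_high_expressers(z, "D", 1.5)
        expected = [f"c{j}" for j in np.flatnonzero(vals[0] > 1.5)]
        assert cells == expected

    def test_sd_zero_driver_flagged(self):
        z = make_z(["D"], [[0.0, 0.0]])
        z.sd_zero[0] = True
        cells, reason = ss.select_high_expressers(z, "D", 1.5)
        assert cells == [] and "zero reference SD" in reason

    def test_absent_driver_flagged(self):
        z = make_z(["D"], [[0.0, 0.0]])
        cells, reason = ss.select_high_expressers(z, "MISSING", 1.5)
        assert cells == [] and "absent" in reason


def exact_ranksum_oracle(x, y):
    """Independent full-enumeration two-sided rank-sum p (tail doubling)."""
    pooled = list(x) + list(y)
    ranks = scipy.stats.rankdata(pooled)
    nx, n = len(x), len(pooled)
    w_obs = sum(ranks[:nx])
    dist = [sum(ranks[list(c)]) for c in itertools.combinations(range(n), nx)]
    le = sum(1 for w in dist if w <= w_obs + 1e-9)
    ge = sum(1 for w in dist if w >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(le, ge) / comb(n, nx))


def _de_dataset(a_vals, b_vals, gene_ids=None):
    """Dataset whose lognorm holds the given per-gene group values."""
    a_vals, b_vals = np.atleast_2d(a_vals), np.atleast_2d(b_vals)
    X = np.hstack([a_vals, b_vals])
    g, n = X.shape
    ds = ss.ExpressionDataset(
        gene_ids or [f"G{i}" for i in range(g)],
        [f"c{j}" for j in range(n)],
        sp.csr_matrix((X > 0).astype(int)),
    )
    ds.lognorm = X.astype(float)
    cells_a = ds.cell_ids[: a_vals.shape[1]]
    cells_b = ds.cell_ids[a_vals.shape[1]:]
    return ds, cells_a, cells_b


class TestWilcoxonDe:
    def test_identical_groups_yield_nothing(self):
        rng = np.random.default_rng(1)
        vals = rng.gamma(2, size=(10, 8))
        ds, a, b = _de_dataset(vals, vals)
        assert wilcoxon_de(ds, a, b) == []

    def test_fully_shifted_gene_hits_exact_tail(self):
        # all group-a values exceed all group-b values, 10 vs 10
        a = np.linspace(3.0, 4.0, 10)[None, :]
        b = np.linspace(0.5, 1.5, 10)[None, :]
        ds, ca, cb = _de_dataset(a, b)
        res = wilcoxon_de(ds, ca, cb, logfc_threshold=0.25, adj_p_max=1.0)
        assert len(res) == 1 and res[0].direction == "up"
        assert res[0].p_value == pytest.approx(2 / comb(20, 10), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_small_n_matches_exact_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(3, 9, size=2)
        # integer-valued data forces ties, exercising mid-rank handling
        a = rng.integers(0, 4, size=(5, na)).astype(float) + 1.0
        b = rng.integers(0, 4, size=(5, nb)).astype(float) + 1.0
        ds, ca, cb = _de_dataset(a, b)
        res = wilcoxon_de(ds, ca, cb, logfc_threshold=0.0, adj_p_max=1.0)
        assert res  # logfc 0 tests every gene
        for r in res:
            g = int(r.gene[1:])
            assert r.p_value == pytest.approx(
                exact_ranksum_oracle(a[g], b[g]), abs=1e-9
            )

    def test_planted_program_recovery(self):
        # 20 planted up genes at true 2-fold change, n=100 per group
        rng = np.random.default_rng(7)
        n_genes, n = 200, 100
        base = rng.uniform(2, 8, size=n_genes)
        mu = np.tile(base[:, None], (1, 2 * n))
        planted = rng.choice(n_genes, size=20, replace=False)
        mu[planted, :n] *= 2.0
        counts = rng.poisson(mu)
        ds = ss.lognormalize(
            ss.ExpressionDataset(
                [f"G{i}" for i in range(n_genes)],
                [f"c{j}" for j in range(2 * n)],
                sp.csr_matrix(counts),
            )
        )
        res = wilcoxon_de(ds, ds.cell_ids[:n], ds.cell_ids[n:],
                          logfc_threshold=0.25, adj_p_max=0.05)
        up = {r.gene for r in res if r.direction == "up"}
        truth = {f"G{i}" for i in planted}
        jaccard = len(up & truth) / len(up | truth)
        assert jaccard >= 0.8

    def test_overlapping_groups_raise(self):
        ds, a, b = _de_dataset(np.ones((2, 5)), np.zeros((2, 5)))
        with pytest.raises(ContractError):
            wilcoxon_de(ds, a, a[:3] + b[:2])


class TestBuildGeneSetPair:
    @staticmethod
    def _boundary_dataset(n_high):
        """Control group of 60 cells plus a senescent group in which exactly
        n_high cells overexpress the driver (with a coupled program gene)."""
        rng = np.random.default_rng(42)
        n_ctrl, n_grp = 60, 120
        counts = np.empty((3, n_ctrl + n_grp), dtype=int)
        counts[0] = 5
        counts[0, :n_ctrl] = rng.integers(4, 7, n_ctrl)  # tight driver baseline
        counts[0, n_ctrl: n_ctrl + n_high] = 200  # high expressers
        counts[1] = rng.poisson(5, n_ctrl + n_grp)
        counts[1, n_ctrl: n_ctrl + n_high] = 80  # coupled program gene
        counts[2] = rng.poisson(100, n_ctrl + n_grp)  # stabilizes library size
        meta = __import__("pandas").DataFrame(
            {"group_label": ["ctrl"] * n_ctrl + ["sen"] * n_grp},
            index=[f"c{j}" for j in range(n_ctrl + n_grp)],
        )
        ds = ss.lognormalize(
            ss.ExpressionDataset(
                ["DRIVER", "PROG", "OTHER"],
                [f"c{j}" for j in range(n_ctrl + n_grp)],
                sp.csr_matrix(counts), cell_meta=meta,
            )
        )
        rs = compute_reference_stats(ds, ds.cells_of_group("ctrl"))
        return ds, zscore_matrix(ds, rs)

    def test_min_cells_boundary(self):
        params = ss.EgsParams(min_cells=50)
        ds, z = self._boundary_dataset(49)
        assert ss.build_gene_set_pair(
            ds, z, "DRIVER", "sen", ds.cells_of_group("ctrl"), params
        ) is None
        ds, z = self._boundary_dataset(50)
        pair = ss.build_gene_set_pair(
            ds, z, "DRIVER", "sen", ds.cells_of_group("ctrl"), params
        )
        assert pair is not None and pair.n_driver_cells == 50
        assert "DRIVER" in pair.up_genes and "PROG" in pair.up_genes

    def test_planted_driver_program_recovered(self, ref_data, ref_model):
        dataset, truth = ref_data
        by_driver = {
            (p.driver, p.group): p for p in ref_model.pairs if p.driver != "lowSASP"
        }
        pair = by_driver[("IGFBP7", "PDL_50np")]
        up_truth = set(truth.driver_programs["IGFBP7"][0])
        assert len(up_truth & set(pair.up_genes)) / len(up_truth) >= 0.8


class TestLowSasp:
    def test_selection_invariant_to_sasp_gene_order(self, ref_data, ref_model):
        dataset, _ = ref_data
        z = zscore_matrix(dataset, ref_model.ref_stats)
        goi = ss.load_genes_of_interest()
        sasp = [g for g in goi if g not in ARREST_GENES]
        params = ss.EgsParams()
        a = select_lowsasp_cells(dataset, z, sasp, "PDL_50np", params)
        b = select_lowsasp_cells(dataset, z, sasp[::-1], "PDL_50np", params)
        assert a == b

    def test_planted_silent_subpopulation_recovered(self, ref_data, ref_model):
        dataset, truth = ref_data
        z = zscore_matrix(dataset, ref_model.ref_stats)
        goi = ss.load_genes_of_interest()
        sasp = [g for g in goi if g not in ARREST_GENES]
        for group in ("PDL_46np", "PDL_50np"):
            selected = set(
                select_lowsasp_cells(dataset, z, sasp, group, ss.EgsParams())
            )
            planted = set(truth.lowsasp_members[group])
            assert len(selected & planted) / len(planted) >= 0.8

    def test_uniformly_high_sasp_group_yields_none(self):
        # every cell expresses the single SASP gene far above reference
        rng = np.random.default_rng(3)
        counts = np.vstack([
            np.r_[rng.integers(2, 5, 30), np.full(40, 200)],
            rng.poisson(100, 70),  # stabilizes library size
        ])
        meta = __import__("pandas").DataFrame(
            {"group_label": ["ctrl"] * 30 + ["sen"] * 40},
            index=[f"c{j}" for j in range(70)],
        )
        ds = ss.lognormalize(ss.ExpressionDataset(
            ["IL6", "OTHER"], [f"c{j}" for j in range(70)],
            sp.csr_matrix(counts), cell_meta=meta,
        ))
        rs = compute_reference_stats(ds, ds.cells_of_group("ctrl"))
        z = zscore_matrix(ds, rs)
        pair = ss.build_lowsasp_pair(
            ds, z, ["IL6"], "sen", ds.cells_of_group("ctrl"),
            ss.EgsParams(min_cells=5),
        )
        assert pair is None


class TestBuildEnsemble:
    def test_pair_set_matches_counting_oracle(self, ref_data, ref_model, genes_of_interest):
        """The (driver, group) combinations with >= min_cells high expressers,
        recomputed densely from scratch, are exactly the pairs built."""
        dataset, _ = ref_data
        X = dataset.lognorm
        ctrl_idx = dataset.cell_indices(dataset.cells_of_group("PDL_25p"))
        mu = X[:, ctrl_idx].mean(axis=1)
        sd = X[:, ctrl_idx].std(axis=1, ddof=1)
        expected = set()
        groups = np.asarray(dataset.cell_meta["group_label"])
        for group in ("PDL_46np", "PDL_50np"):
            gmask = groups == group
            for gene in genes_of_interest:
                if not dataset.has_gene(gene):
                    continue
                gi = dataset.gene_index(gene)
                if sd[gi] == 0:
                    continue
                n_high = int(((X[gi, gmask] - mu[gi]) / sd[gi] > 1.5).sum())
                if n_high >= 50:
                    expected.add((gene, group))
        built = {(p.driver, p.group) for p in ref_model.pairs if p.driver != "lowSASP"}
        assert built == expected

    def test_bit_stable_across_runs(self, ref_data, genes_of_interest):
        dataset, _ = ref_data
        kwargs = dict(
            genes_of_interest=genes_of_interest,
            groups=["PDL_46np", "PDL_50np"],
            control_group="PDL_25p",
            params=ss.EgsParams(),
        )
        a = ss.build_ensemble(dataset, **kwargs)
        b = ss.build_ensemble(dataset, **kwargs)
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(
            b.to_dict(), sort_keys=True
        )

    def test_program_identifiability(self, ref_model, ref_data):
        """Each driver's pair resembles its own planted program more than any
        other driver's program."""
        _, truth = ref_data

        def jac(a, b):
            a, b = set(a), set(b)
            return len(a & b) / len(a | b) if a | b else 0.0

        for pair in ref_model.pairs:
            if pair.driver not in truth.driver_programs:
                continue
            own = jac(pair.up_genes, truth.driver_programs[pair.driver][0])
            others = [
                jac(pair.up_genes, prog[0])
                for d, prog in truth.driver_programs.items()
                if d != pair.driver
            ]
            assert own > max(others)

    def test_unreachable_min_cells_raises(self, ref_data, genes_of_interest):
        dataset, _ = ref_data
        with pytest.raises(ContractError, match="no gene-set pair"):
            ss.build_ensemble(
                dataset, genes_of_interest, ["PDL_46np", "PDL_50np"],
                "PDL_25p", ss.EgsParams(min_cells=10_000),
            )

    def test_model_json_round_trip(self, ref_model, tmp_path):
        path = tmp_path / "model.json"
        ref_model.to_json(path)
        back = ss.EnsembleModel.from_json(path)
        assert back.to_dict() == ref_model.to_dict()
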