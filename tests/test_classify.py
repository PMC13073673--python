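"""Two-Gaussian threshold fitting, cross-validation, and confident selection."""

import numpy as np
import pytest
import scipy.stats

import senescore as ss
from senescore.classify import kfold_cv, select_confident
from senescore.datatypes import ContractError

GRID_STEP_FACTOR = 1e-3  # 2001-point grid resolution relative to its span


def _sample_with_moments(rng, n, mu, sd):
    """A sample whose empirical mean/SD (ddof=1) are exactly mu/sd."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mu + sd * x


class TestFitGaussianThreshold:
    def test_symmetric_case_reproduces_2p1(self):
        """ctrl ~ N(0,1) vs sen ~ N(4.2,1) with equal n: the expected-error
        minimum sits at the midpoint 2.1."""
        rng = np.random.default_rng(0)
        ctrl = _sample_with_moments(rng, 500, 0.0, 1.0)
        sen = _sample_with_moments(rng, 500, 4.2, 1.0)
        fit = ss.fit_gaussian_threshold(ctrl, sen)
        step = (fit.mu_sen + 3 * fit.sd_sen - (fit.mu_ctrl - 3 * fit.sd_ctrl)) / 2000
        assert fit.threshold == pytest.approx(2.1, abs=step + 1e-12)

    @pytest.mark.parametrize("mu_c,mu_s,sd", [(0, 4, 1), (-2, 3, 0.5), (1, 1.5, 0.1)])
    def test_equal_variance_equal_n_gives_midpoint(self, mu_c, mu_s, sd):
        rng = np.random.default_rng(1)
        ctrl = _sample_with_moments(rng, 300, mu_c, sd)
        sen = _sample_with_moments(rng, 300, mu_s, sd)
        fit = ss.fit_gaussian_threshold(ctrl, sen)
        step = (fit.mu_sen + 3 * fit.sd_sen - (fit.mu_ctrl - 3 * fit.sd_ctrl)) / 2000
        assert fit.threshold == pytest.approx((mu_c + mu_s) / 2, abs=step + 1e-12)

    @pytest.mark.parametrize(
        "n_c,mu_c,sd_c,n_s,mu_s,sd_s",
        [(200, 0.0, 1.0, 100, 3.0, 2.0), (500, 0.0, 0.8, 100, 2.5, 1.5),
         (100, -1.0, 1.2, 400, 2.0, 0.7)],
    )
    def test_matches_analytic_density_crossing(self, n_c, mu_c, sd_c, n_s, mu_s, sd_s):
        """With unequal n or SD the optimum solves
        n_c phi_c(t) = n_s phi_s(t); compare against the quadratic's root."""
        rng = np.random.default_rng(2)
        ctrl = _sample_with_moments(rng, n_c, mu_c, sd_c)
        sen = _sample_with_moments(rng, n_s, mu_s, sd_s)
        fit = ss.fit_gaussian_threshold(ctrl, sen)
        # roots of: log(n_c) + log phi_c(t) = log(n_s) + log phi_s(t)
        a = 1 / (2 * sd_s**2) - 1 / (2 * sd_c**2)
        b = mu_c / sd_c**2 - mu_s / sd_s**2
        c = (mu_s**2 / (2 * sd_s**2) - mu_c**2 / (2 * sd_c**2)
             + np.log(n_c / n_s) + np.log(sd_s / sd_c))
        roots = np.roots([a, b, c]) if a != 0 else np.array([-c / b])
        roots = roots[(roots > mu_c) & (roots < mu_s)]
        assert roots.size == 1
        step = (fit.mu_sen + 3 * fit.sd_sen - (fit.mu_ctrl - 3 * fit.sd_ctrl)) / 2000
        assert fit.threshold == pytest.approx(float(roots[0]), abs=step + 1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        ctrl = _sample_with_moments(rng, 150, 0.0, 1.0)
        sen = _sample_with_moments(rng, 150, 3.0, 1.5)
        base = ss.fit_gaussian_threshold(ctrl, sen).threshold
        shifted = ss.fit_gaussian_threshold(ctrl + 5.0, sen + 5.0).threshold
        assert shifted == pytest.approx(base + 5.0, abs=1e-9)

    def test_more_senescent_weight_lowers_threshold(self):
        rng = np.random.default_rng(4)
        ctrl = _sample_with_moments(rng, 200, 0.0, 1.0)
        sen = _sample_with_moments(rng, 100, 3.0, 1.0)
        t1 = ss.fit_gaussian_threshold(ctrl, sen).threshold
        t2 = ss.fit_gaussian_threshold(ctrl, np.tile(sen, 4)).threshold
        assert t2 <= t1

    def test_equal_priors_weighting_ignores_counts(self):
        rng = np.random.default_rng(5)
        ctrl = _sample_with_moments(rng, 1000, 0.0, 1.0)
        sen = _sample_with_moments(rng, 50, 3.0, 1.0)
        t_eq = ss.fit_gaussian_threshold(ctrl, sen, weighting="equal").threshold
        step = 1e-2
        assert t_eq == pytest.approx(1.5, abs=step)

    def test_bayes_error_at_large_n(self):
        """Threshold classification reaches the two-Gaussian Bayes error."""
        rng = np.random.default_rng(6)
        n = 100_000
        ctrl = rng.normal(0.0, 1.0, n)
        sen = rng.normal(3.0, 1.0, n)
        fit = ss.fit_gaussian_threshold(ctrl, sen)
        err = ((ctrl > fit.threshold).sum() + (sen <= fit.threshold).sum()) / (2 * n)
        bayes = scipy.stats.norm.cdf(-1.5)
        assert err == pytest.approx(bayes, abs=0.01)

    def test_reversed_means_raise(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ContractError, match="swapped"):
            ss.fit_gaussian_threshold(
                _sample_with_moments(rng, 50, 2.0, 1.0),
                _sample_with_moments(rng, 50, 0.0, 1.0),
            )


class TestClassifyCells:
    def test_boundary_is_normal(self):
        assert not ss.classify_cells([2.1], 2.1)[0]

    def test_all_below_means_no_senescent(self):
        assert ss.classify_cells([0.1, -3.0, 2.0], 2.1).sum() == 0

    def test_matches_comparison_oracle(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=500)
        labels = ss.classify_cells(scores, 0.3)
        np.testing.assert_array_equal(labels, [s > 0.3 for s in scores])


class TestSelectConfident:
    @staticmethod
    def _fixture(n_cells=300, seed=9):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n_cells)
        p21 = rng.integers(0, 2, n_cells) * rng.integers(0, 4, n_cells)
        p16 = (rng.random(n_cells) < 0.2) * rng.integers(1, 3, n_cells)
        cells = [f"c{j:03d}" for j in range(n_cells)]
        return scores, cells, p21, p16

    def test_matches_sort_oracle(self):
        scores, cells, p21, p16 = self._fixture()
        sel = select_confident(scores, cells, p21, p16, 30)
        pos = (np.asarray(p21) > 0) | (np.asarray(p16) > 0)
        neg_sorted = sorted(
            (s, c) for s, c, p in zip(scores, cells, pos) if not p
        )
        pos_sorted = sorted((s, c) for s, c, p in zip(scores, cells, pos) if p)
        assert sel.low_cells == [c for _, c in neg_sorted[:30]]
        assert sel.high_cells == [c for _, c in pos_sorted[-30:]]

    def test_all_p21_positive_raises(self):
        scores = [1.0, 2.0, 3.0]
        with pytest.raises(ContractError, match="p21-/p16-"):
            select_confident(scores, ["a", "b", "c"], [1, 2, 1], [0, 0, 0], 1)

    def test_n_equal_to_stratum_size_takes_whole_stratum(self):
        scores = [0.0, 1.0, 2.0, 3.0]
        sel = select_confident(
            scores, list("abcd"), [0, 0, 1, 2], [0, 0, 0, 0], 2
        )
        assert set(sel.low_cells) == {"a", "b"}
        assert set(sel.high_cells) == {"c", "d"}

    def test_invariant_to_cell_order(self):
        scores, cells, p21, p16 = self._fixture()
        sel = select_confident(scores, cells, p21, p16, 25)
        rng = np.random.default_rng(10)
        perm = rng.permutation(len(cells))
        sel2 = select_confident(
            np.asarray(scores)[perm], [cells[i] for i in perm],
            np.asarray(p21)[perm], np.asarray(p16)[perm], 25,
        )
        assert sel.low_cells == sel2.low_cells
        assert sel.high_cells == sel2.high_cells


class TestKfoldCv:
    def test_deterministic_given_seed(self, ref_data, genes_of_interest):
        dataset, _ = ref_data
        params = ss.EgsParams(rng_seed=13)
        a = kfold_cv(dataset, genes_of_interest, "PDL_25p", params)
        b = kfold_cv(dataset, genes_of_interest, "PDL_25p", params)
        assert a.to_dict() == b.to_dict()

    def test_permuted_labels_give_chance_extremes(self, ref_data, genes_of_interest):
        dataset, _ = ref_data
        rng = np.random.default_rng(21)
        meta = dataset.cell_meta.copy()
        # balanced random relabeling: class labels carry no information, so
        # chance level is exactly 50%
        meta["group_label"] = rng.choice(["PDL_25p", "PDL_50np"], dataset.n_cells)
        permuted = ss.ExpressionDataset(
            dataset.gene_ids, dataset.cell_ids, dataset.counts,
            cell_meta=meta, lognorm=dataset.lognorm,
        )
        report = kfold_cv(permuted, genes_of_interest, "PDL_25p", ss.EgsParams())
        acc = report.mean_extremes_accuracy
        assert 0.35 <= acc <= 0.65
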