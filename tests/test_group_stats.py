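"""Gated group comparison, BH-FDR, Friedman/Kendall-W and cost-AUC."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from dfcomplexity import (
    InsufficientDataError,
    auc_over_costs,
    compare_groups,
    fdr_bh,
    friedman_kendall,
)
from dfcomplexity.graphs import CostGrid


def brute_fdr_bh(pvals, alpha):
    """Largest rejection set satisfying the BH criterion, by exhaustive
    search over all candidate set sizes."""
    p = np.asarray(pvals)
    order = np.argsort(p, kind="stable")
    best_k = 0
    for k in range(1, len(p) + 1):
        if p[order[k - 1]] <= alpha * k / len(p):
            best_k = k
    mask = np.zeros(len(p), dtype=bool)
    mask[order[:best_k]] = True
    return mask


def brute_friedman_w(values):
    """Kendall's W from first principles: midranks within subjects,
    variance of rank sums with tie correction, chi2 = n (k-1) W."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    ranks = np.vstack([rankdata(row) for row in values])
    col_sums = ranks.sum(axis=0)
    s = np.sum((col_sums - n * (k + 1) / 2) ** 2)
    ties = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    w = 12 * s / (n**2 * (k**3 - k) - n * ties)
    return n * (k - 1) * w, w


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = compare_groups(a, a)
        assert res.p > 0.99

    def test_separated_normals_use_t_branch(self, rng):
        a = rng.normal(0, 1, 14)
        b = rng.normal(3, 1, 14)
        res = compare_groups(a, b)
        assert res.test_name == "t"
        assert res.p < 1e-3

    def test_heavy_tails_use_mwu_branch(self, rng):
        a = rng.standard_cauchy(50)
        b = rng.standard_cauchy(50)
        assert compare_groups(a, b).test_name == "mwu"

    def test_zero_variance_goes_nonparametric(self):
        res = compare_groups([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert res.test_name == "mwu"

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(99)
        rejections = sum(
            compare_groups(rng.normal(size=14), rng.normal(size=14)).p < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


class TestFdrBH:
    def test_step_up_rescues_trailing_pvalues(self):
        mask = fdr_bh([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert mask.all()  # p_(4) = 0.04 <= 0.05 -> all rejected

    def test_all_ones_rejects_nothing(self):
        assert not fdr_bh(np.ones(6)).any()

    def test_single_p_reduces_to_alpha_test(self):
        assert fdr_bh([0.049]).all()
        assert not fdr_bh([0.051]).any()

    def test_matches_brute_force_and_statsmodels(self, rng):
        for m in (1, 3, 7, 10):
            for _ in range(30):
                p = rng.uniform(size=m)
                ours = fdr_bh(p, 0.05)
                np.testing.assert_array_equal(ours, brute_fdr_bh(p, 0.05))
                sm = multipletests(p, alpha=0.05, method="fdr_bh")[0]
                np.testing.assert_array_equal(ours, sm)


class TestFriedmanKendall:
    def test_perfect_concordance(self):
        values = np.tile(np.arange(8, dtype=float), (14, 1)) + \
            np.arange(14)[:, None]
        chi2, p, w = friedman_kendall(values)
        assert w == pytest.approx(1.0)
        assert p < 1e-10

    def test_identity_between_chi2_and_w(self, rng):
        values = rng.standard_normal((14, 8))
        chi2, _, w = friedman_kendall(values)
        assert chi2 == pytest.approx(w * 14 * 7)

    def test_null_concordance_is_small(self):
        ws = []
        for seed in range(100):
            values = np.random.default_rng(seed).standard_normal((14, 8))
            ws.append(friedman_kendall(values)[2])
        assert np.median(ws) < 0.2

    def test_matches_first_principles_formula(self, rng):
        for _ in range(20):
            values = rng.standard_normal((10, 5))
            chi2, _, w = friedman_kendall(values)
            chi2_ref, w_ref = brute_friedman_w(values)
            assert chi2 == pytest.approx(chi2_ref, rel=1e-10)
            assert w == pytest.approx(w_ref, rel=1e-10)

    def test_constant_rows_handled(self):
        values = np.ones((5, 4))
        chi2, p, w = friedman_kendall(values)
        assert (chi2, p, w) == (0.0, 1.0, 0.0)


class TestAUC:
    def test_constant_value_over_default_grid(self):
        costs = list(CostGrid())
        assert auc_over_costs(np.full(8, 2.0), costs) == pytest.approx(0.7)
        assert auc_over_costs(np.full(8, 1.0), costs) == pytest.approx(0.35)

    def test_identity_curve_exact_integral(self):
        costs = np.array(list(CostGrid()))
        expected = (0.5**2 - 0.15**2) / 2
        assert auc_over_costs(costs, costs) == pytest.approx(expected)

    def test_linearity_in_values(self, rng):
        costs = list(CostGrid())
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        assert auc_over_costs(a + b, costs) == pytest.approx(
            auc_over_costs(a, costs) + auc_over_costs(b, costs)
        )

    def test_single_cost_rejected(self):
        with pytest.raises(InsufficientDataError):
            auc_over_costs([1.0], [0.35])
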