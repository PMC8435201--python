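"""delta-lnL conventions, RELL bootstrap, AU test, and BIC posteriors."""

import numpy as np
import pytest
from scipy.stats import kstest

from toposcope.seqio import SiteLnLMatrix, parse_newick
from toposcope.synthetic_data import simulate_alignment, simulate_site_lnl
from toposcope.topo_tests import (
    au_test,
    bic_posteriors,
    delta_lnl,
    rell_bootstrap,
    run_topology_tests,
    topology_tests_from_matrix,
)

# Published comparison table used as arithmetic input: four fully
# constrained topologies and their total log-likelihoods.
TABLE_LNL = {
    "T0": -375_741.33,
    "T1": -375_740.41,
    "T2": -375_844.52,
    "T3": -375_944.68,
}


class TestDeltaLnL:
    def test_table_convention_matches_published_ratios(self):
        assert delta_lnl(TABLE_LNL["T0"], TABLE_LNL["T2"], "table") == pytest.approx(103.19)
        assert delta_lnl(TABLE_LNL["T0"], TABLE_LNL["T3"], "table") == pytest.approx(203.35)
        assert delta_lnl(TABLE_LNL["T0"], TABLE_LNL["T1"], "table") == pytest.approx(-0.92)

    def test_equation_convention(self):
        # 2*(lnL_alt - lnL_null) on the same printed numbers
        assert delta_lnl(TABLE_LNL["T0"], TABLE_LNL["T1"], "equation") == pytest.approx(1.84)
        assert delta_lnl(TABLE_LNL["T0"], TABLE_LNL["T2"], "equation") == pytest.approx(-206.38)

    def test_identical_trees_zero_under_both(self):
        assert delta_lnl(-5.0, -5.0, "table") == 0.0
        assert delta_lnl(-5.0, -5.0, "equation") == 0.0

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            delta_lnl(-1.0, -2.0, "bogus")

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            delta_lnl(float("-inf"), -2.0, "table")


class TestRELL:
    def test_single_site_replicates_constant(self):
        m = SiteLnLMatrix(["a", "b"], np.array([[-1.5], [-2.5]]))
        reps = rell_bootstrap(m, n_boot=50, seed=0)
        assert np.all(reps[0] == -1.5) and np.all(reps[1] == -2.5)

    def test_constant_rows_give_exact_totals(self):
        m = SiteLnLMatrix(["t1", "t2"], np.array([[0.0, 0.0], [-1.0, -1.0]]))
        reps = rell_bootstrap(m, n_boot=100, seed=1)
        assert np.all(reps[0] == 0.0) and np.all(reps[1] == -2.0)

    def test_replicate_mean_within_multinomial_se(self):
        """Moment oracle: E[replicate total] = observed total; SE of the
        replicate mean over B draws is sqrt(n * popvar(site lnls) / B)."""
        m = SiteLnLMatrix(["x", "y"], np.array([[-1.0, -3.0, -2.0], [-0.5, -0.5, -4.0]]))
        B = 100_000
        reps = rell_bootstrap(m, n_boot=B, seed=3)
        for row, rep in zip(m.values, reps):
            n = row.size
            se = np.sqrt(n * row.var() / B)
            assert abs(rep.mean() - row.sum()) < 4 * se

    def test_replicates_bounded_by_site_extremes(self):
        m = simulate_site_lnl(3, 50, [0.0, 0.1, -0.1], 0.5, seed=5)
        reps = rell_bootstrap(m, n_boot=500, seed=6)
        n = m.n_sites
        for row, rep in zip(m.values, reps):
            assert np.all(rep >= n * row.min() - 1e-9)
            assert np.all(rep <= n * row.max() + 1e-9)

    def test_seed_reproducibility(self):
        m = simulate_site_lnl(2, 20, [0.0, 0.0], 1.0, seed=7)
        a = rell_bootstrap(m, n_boot=64, seed=11)
        b = rell_bootstrap(m, n_boot=64, seed=11)
        assert np.array_equal(a, b)

    def test_empty_matrix_rejected(self):
        m = SiteLnLMatrix(["a"], np.empty((1, 0)))
        with pytest.raises(ValueError):
            rell_bootstrap(m, n_boot=10, seed=0)


class TestAU:
    def test_dominating_tree_saturates(self):
        n = 200
        base = -2.0 * np.ones(n)
        m = SiteLnLMatrix(["win", "lose"], np.vstack([base + 1.0, base]))
        p = au_test(m, n_boot_per_scale=1000, seed=0)
        assert p["win"] >= 0.999
        assert p["lose"] <= 0.001

    def test_identical_rows_near_half(self):
        row = -np.abs(np.random.default_rng(9).normal(2, 1, 300))
        m = SiteLnLMatrix(["a", "b"], np.vstack([row, row]))
        p = au_test(m, n_boot_per_scale=10_000, seed=4)
        assert abs(p["a"] - 0.5) < 0.05
        assert abs(p["b"] - 0.5) < 0.05

    def test_single_scale_reduces_to_naive_proportion(self):
        rng = np.random.default_rng(12)
        base = rng.normal(-3, 1, 400)
        m = SiteLnLMatrix(
            ["a", "b"], np.minimum(np.vstack([base + rng.normal(0, 0.4, 400),
                                              base + rng.normal(0, 0.4, 400)]), 0)
        )
        B = 100_000
        p = au_test(m, scales=(1.0,), n_boot_per_scale=B, seed=13)
        reps = rell_bootstrap(m, n_boot=B, seed=13)
        naive = (reps[0] > reps[1]).mean()
        # same resampling scheme, independent draws: agreement to MC error
        assert abs(p["a"] - naive) < 4 * np.sqrt(naive * (1 - naive) / B) + 0.01

    def test_fewer_than_two_trees_rejected(self):
        m = SiteLnLMatrix(["only"], np.array([[-1.0, -2.0]]))
        with pytest.raises(ValueError):
            au_test(m, seed=0)

    def test_p_values_in_unit_interval(self):
        m = simulate_site_lnl(4, 100, [0.0, 0.05, -0.05, 0.2], 1.0, seed=21)
        p = au_test(m, n_boot_per_scale=500, seed=22)
        assert all(0.0 <= v <= 1.0 for v in p.values())

    def test_null_p_values_approximately_uniform(self):
        """Under zero between-tree effect the AU p-value of a tree should
        be uniform across simulated datasets (KS at the 1% level)."""
        rng = np.random.default_rng(2030)
        pvals = []
        for _ in range(100):
            base = rng.normal(-3, 1, 200)
            diff = rng.normal(0, 1, 200)  # iid site differences, zero mean
            m = SiteLnLMatrix("ab", np.vstack([base, base + diff]))
            p = au_test(m, n_boot_per_scale=1000, seed=rng.integers(2**31))
            pvals.append(p["a"])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestBIC:
    def test_published_table_posteriors(self):
        lnls = [TABLE_LNL[t] for t in ("T0", "T1", "T2", "T3")]
        post = bic_posteriors(lnls)
        # printed-precision check: tiny entries to one significant figure
        assert post[0] == pytest.approx(0.285, abs=0.001)
        assert post[1] == pytest.approx(0.715, abs=0.001)
        assert float(f"{post[2]:.0e}") == 4e-46
        assert float(f"{post[3]:.0e}") == 1e-89

    def test_equal_lnls_uniform(self):
        assert np.allclose(bic_posteriors([-7.0] * 5), 0.2)

    def test_two_tree_closed_form(self):
        for delta in (0.3, 2.0, 10.0):
            post = bic_posteriors([0.0, delta])
            expected = np.array([1 / (1 + np.exp(delta)), np.exp(delta) / (1 + np.exp(delta))])
            assert np.max(np.abs(post - expected)) < 1e-12

    def test_shift_invariance(self):
        lnls = np.array([-10.0, -12.5, -11.1])
        assert np.max(np.abs(bic_posteriors(lnls) - bic_posteriors(lnls + 1e4))) < 1e-12

    def test_posteriors_sum_to_one_even_when_far_apart(self):
        post = bic_posteriors([-1e6, -2e6, -1e6 + 1])
        assert abs(post.sum() - 1.0) < 1e-12

    def test_unequal_penalties_shift_weight(self):
        post = bic_posteriors([0.0, 0.0], penalty_terms=[0.0, 2.0])
        assert post[0] > post[1]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bic_posteriors([-1.0, float("nan")])


class TestOrchestration:
    def test_identical_trees_split_posterior(self):
        row = np.random.default_rng(31).normal(-3, 1, 100).clip(max=0)
        m = SiteLnLMatrix(["t0", "t1"], np.vstack([row, row]))
        res = topology_tests_from_matrix(m, "t0", n_boot=500, seed=1)
        assert res.delta_lnl_table["t1"] == pytest.approx(0.0, abs=1e-9)
        assert res.bic_posterior["t0"] == pytest.approx(0.5, abs=1e-12)

    def test_null_delta_zero_by_construction(self):
        m = simulate_site_lnl(3, 80, [0.0, 0.2, -0.2], 0.8, seed=41)
        res = topology_tests_from_matrix(m, "T0", n_boot=500, seed=2)
        assert res.delta_lnl_table["T0"] == 0.0
        assert res.delta_lnl_equation["T0"] == 0.0

    def test_missing_null_rejected(self):
        m = simulate_site_lnl(2, 10, [0.0, 0.0], 1.0, seed=3)
        with pytest.raises(ValueError):
            topology_tests_from_matrix(m, "nope", seed=0)

    def test_recovers_generating_topology(self, lg_model):
        """End-to-end: data simulated on a known quartet; the true topology
        wins the BIC posterior and the wrong one is rejected by AU."""
        true = parse_newick("((A:0.3,B:0.3):0.15,(C:0.3,D:0.3):0.15);")
        wrong = parse_newick("((A:0.3,C:0.3):0.15,(B:0.3,D:0.3):0.15);")
        aln = simulate_alignment(true, lg_model, 1000, seed=77)
        result, matrix = run_topology_tests(
            aln, {"true": true, "wrong": wrong}, lg_model,
            null_id="true", n_boot=2000, seed=8, brlen_tol=1e-3,
        )
        assert result.bic_posterior["true"] > 0.95
        assert result.au_p["wrong"] < 0.05
        assert matrix.totals()[0] > matrix.totals()[1]
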