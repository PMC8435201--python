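"""Likelihood-engine oracles: closed forms, enumeration, and recovery."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from toposcope.alphabets import AMINO_ACID, BINARY, NUCLEOTIDE
from toposcope.errors import OptimizationError
from toposcope.phylo_likelihood import (
    SubstitutionModel,
    discrete_gamma_rates,
    empirical_frequencies,
    optimize_branch_lengths,
    optimize_gamma_shape,
    site_log_likelihoods,
    transition_probabilities,
    tree_log_likelihood,
)
from toposcope.seqio import Alignment, parse_newick
from toposcope.synthetic_data import simulate_alignment


class TestDiscreteGamma:
    def test_single_category_is_rate_one(self):
        rates, weights = discrete_gamma_rates(0.7, 1)
        assert rates.tolist() == [1.0] and weights.tolist() == [1.0]

    def test_vanishing_heterogeneity_limit(self):
        rates, _ = discrete_gamma_rates(1e6, 4)
        assert np.all(np.abs(rates - 1.0) < 1e-2)

    def test_mean_rate_is_one(self):
        for alpha in (0.1, 0.5, 2.0, 17.0):
            rates, weights = discrete_gamma_rates(alpha, 4)
            assert abs((rates * weights).sum() - 1.0) < 1e-10

    def test_category_means_match_quadrature(self):
        # Independent oracle: numerically integrate x*pdf over each
        # quantile bin of Gamma(alpha, rate alpha) and divide by the bin mass.
        alpha, n = 0.5, 4
        rates, _ = discrete_gamma_rates(alpha, n)
        cuts = np.r_[0.0, gamma_dist.ppf(np.arange(1, n) / n, a=alpha, scale=1 / alpha), np.inf]
        for ci in range(n):
            integral, _ = quad(
                lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha),
                cuts[ci], min(cuts[ci + 1], 1e3),
            )
            assert abs(rates[ci] - integral * n) < 1e-6

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(0.0, 4)


class TestEmpiricalFrequencies:
    def test_counting_oracle(self, make_aln):
        rng = np.random.default_rng(3)
        symbols = np.array(list(AMINO_ACID.states))
        data = symbols[rng.integers(0, 20, size=(4, 200))]
        aln = Alignment(["a", "b", "c", "d"], data, AMINO_ACID)
        freqs = empirical_frequencies(aln)
        counts = np.array([(data == s).sum() for s in AMINO_ACID.states], float)
        if np.all(counts > 0):
            assert np.allclose(freqs, counts / counts.sum(), atol=1e-12)

    def test_single_residue_alignment(self, make_aln):
        aln = make_aln({"x": "AAAA"})
        freqs = empirical_frequencies(aln)
        assert freqs.argmax() == AMINO_ACID.index("A")
        assert abs(freqs.sum() - 1.0) < 1e-12
        # all unseen states share the pseudo-frequency
        assert len(set(np.round(np.delete(freqs, 0), 15))) == 1

    def test_uniform_when_equal_counts(self):
        aln = Alignment(["t"], np.array([list(AMINO_ACID.states)]), AMINO_ACID)
        assert np.allclose(empirical_frequencies(aln), 1 / 20, atol=1e-12)

    def test_all_missing_rejected(self, make_aln):
        aln = make_aln({"x": "??--XX"})
        with pytest.raises(ValueError):
            empirical_frequencies(aln)


class TestTransitionProbabilities:
    def test_zero_branch_is_identity(self, lg_model):
        assert np.allclose(transition_probabilities(lg_model, 0.0), np.eye(20), atol=1e-12)

    def test_long_branch_reaches_stationarity(self, lg_model):
        p = transition_probabilities(lg_model, 1e3)
        assert np.all(np.abs(p - lg_model.frequencies[None, :]) < 1e-6)

    def test_rows_sum_to_one(self, lg_model):
        for t in (0.01, 0.3, 2.5):
            p = transition_probabilities(lg_model, t)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(p >= 0)

    def test_poisson_closed_form(self):
        # Equal-rates CTMC: P_ii = 1/k + (1-1/k) exp(-k t / (k-1))
        model = SubstitutionModel.poisson(NUCLEOTIDE)
        k, t = 4, 0.1
        p = transition_probabilities(model, t)
        diag = 1 / k + (1 - 1 / k) * np.exp(-k * t / (k - 1))
        off = (1 - diag) / (k - 1)
        expected = np.full((k, k), off)
        np.fill_diagonal(expected, diag)
        assert np.max(np.abs(p - expected)) < 1e-10

    def test_rate_normalization(self, lg_model):
        q = lg_model.rate_matrix()
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-10)
        assert abs(-(lg_model.frequencies * np.diag(q)).sum() - 1.0) < 1e-10


def _brute_force_quartet_lnl(tree_newick, pattern, model, lengths):
    """Exhaustive sum over internal-state assignments for ((A,B),(C,D));
    lengths = (a, b, ab, c, d, cd) with the root on the (AB)-(CD) edge
    split into ab and cd."""
    k = model.k
    pa = transition_probabilities(model, lengths[0])
    pb = transition_probabilities(model, lengths[1])
    pab = transition_probabilities(model, lengths[2])
    pc = transition_probabilities(model, lengths[3])
    pd = transition_probabilities(model, lengths[4])
    pcd = transition_probabilities(model, lengths[5])
    a, b, c, d = pattern
    total = 0.0
    for r, x, y in itertools.product(range(k), repeat=3):
        total += (
            model.frequencies[r]
            * pab[r, x] * pa[x, a] * pb[x, b]
            * pcd[r, y] * pc[y, c] * pd[y, d]
        )
    return np.log(total)


class TestPruning:
    def test_single_leaf_is_log_pi(self, lg_model, make_aln):
        tree = parse_newick("A:0.3;")
        aln = make_aln({"A": "W"})
        lnl = site_log_likelihoods(aln, tree, lg_model)
        assert np.allclose(lnl, np.log(lg_model.frequencies[AMINO_ACID.index("W")]))

    def test_zero_branches_conflicting_states_give_neg_inf(self, make_aln):
        model = SubstitutionModel.poisson(BINARY)
        tree = parse_newick("(A:0.0,B:0.0);")
        aln = Alignment(["A", "B"], np.array([["0"], ["1"]]), BINARY)
        lnl = site_log_likelihoods(aln, tree, model)
        assert lnl[0] == -np.inf  # probability zero, not an exception

    def test_ambiguous_symbols_contribute_one(self, lg_model, make_aln):
        aln_obs = make_aln({"A": "W", "B": "W"})
        aln_miss = make_aln({"A": "W", "B": "?"})
        tree = parse_newick("(A:0.2,B:0.2);")
        lnl_miss = site_log_likelihoods(aln_miss, tree, lg_model)
        # marginalizing B gives exactly the single-taxon likelihood
        assert np.allclose(lnl_miss, np.log(lg_model.frequencies[AMINO_ACID.index("W")]))
        # observing B adds information: the joint lnL is strictly smaller
        assert site_log_likelihoods(aln_obs, tree, lg_model)[0] < lnl_miss[0]

    @pytest.mark.parametrize("alphabet", [BINARY, NUCLEOTIDE])
    def test_pruning_matches_enumeration_all_quartets(self, alphabet):
        """On all 3 distinct unrooted quartets x 10 random length draws the
        pruned lnL equals the exhaustive internal-state enumeration."""
        model = SubstitutionModel.poisson(alphabet)
        rng = np.random.default_rng(42)
        quartets = {
            "((A:{a},B:{b}):{u},(C:{c},D:{d}):{v});": "ABCD",
            "((A:{a},C:{b}):{u},(B:{c},D:{d}):{v});": "ACBD",
            "((A:{a},D:{b}):{u},(B:{c},C:{d}):{v});": "ADBC",
        }
        for newick_tpl, order in quartets.items():
            for _ in range(10):
                lens = dict(zip("abucdv", rng.uniform(0.01, 1.5, 6)))
                tree = parse_newick(newick_tpl.format(**lens))
                states = rng.integers(0, alphabet.k, size=4)
                rows = {
                    t: alphabet.states[s] for t, s in zip(order, states)
                }
                aln = Alignment(
                    ["A", "B", "C", "D"],
                    np.array([[rows[t]] for t in "ABCD"]),
                    alphabet,
                )
                lnl = site_log_likelihoods(aln, tree, model)[0]
                brute = _brute_force_quartet_lnl(
                    newick_tpl, states, model,
                    (lens["a"], lens["b"], lens["u"], lens["c"], lens["d"], lens["v"]),
                )
                assert abs(lnl - brute) < 1e-10

    def test_rerooting_invariance(self, lg_model):
        """Pulley principle: the per-site lnL is identical for any rooting
        of the same unrooted tree under a reversible model."""
        rootings = [
            "((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.05);",
            "(A:0.05,(B:0.2,(C:0.3,D:0.15):0.1):0.05);",
            "(B:0.1,(A:0.1,(C:0.3,D:0.15):0.1):0.1);",
            "(C:0.15,(D:0.15,(A:0.1,B:0.2):0.1):0.15);",
            "(((A:0.1,B:0.2):0.1,C:0.3):0.075,D:0.075);",
        ]
        rng = np.random.default_rng(0)
        symbols = np.array(list(AMINO_ACID.states))
        aln = Alignment(
            ["A", "B", "C", "D"], symbols[rng.integers(0, 20, (4, 40))], AMINO_ACID
        )
        reference = None
        for nwk in rootings:
            lnl = site_log_likelihoods(aln, parse_newick(nwk), lg_model)
            if reference is None:
                reference = lnl
            else:
                assert np.max(np.abs(lnl - reference)) < 1e-10

    def test_missing_leaf_row_rejected(self, lg_model, make_aln):
        aln = make_aln({"A": "W"})
        with pytest.raises(ValueError):
            site_log_likelihoods(aln, parse_newick("(A:0.1,Z:0.1);"), lg_model)


class TestTotalLnL:
    def test_zero_sites_total_zero(self, lg_model):
        aln = Alignment(["A", "B"], np.empty((2, 0), dtype="<U1"), AMINO_ACID)
        tree = parse_newick("(A:0.1,B:0.1);")
        assert tree_log_likelihood(aln, tree, lg_model) == 0.0

    def test_column_duplication_doubles_lnl(self, lg_model, tiny_aa_alignment):
        tree = parse_newick("(A:0.2,(B:0.1,C:0.3):0.1);")
        doubled = Alignment(
            tiny_aa_alignment.taxa,
            np.hstack([tiny_aa_alignment.data, tiny_aa_alignment.data]),
            AMINO_ACID,
        )
        single = tree_log_likelihood(tiny_aa_alignment, tree, lg_model)
        assert abs(tree_log_likelihood(doubled, tree, lg_model) - 2 * single) < 1e-8

    def test_total_equals_site_sum(self, lg_model):
        tree = parse_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        aln = simulate_alignment(tree, lg_model, 500, seed=5)
        sites = site_log_likelihoods(aln, tree, lg_model)
        assert abs(tree_log_likelihood(aln, tree, lg_model) - sites.sum()) < 1e-8


class TestBranchOptimization:
    def test_two_taxon_length_recovery(self):
        model = SubstitutionModel.named("LG")
        true = parse_newick("(A:0.1,B:0.1);")  # total path 0.2
        aln = simulate_alignment(true, model, 5000, seed=123)
        start = parse_newick("(A:0.05,B:0.05);")
        fitted, _ = optimize_branch_lengths(aln, start, model)
        total_path = sum(
            n.length for n in fitted.root.postorder() if n.parent is not None
        )
        assert abs(total_path - 0.2) / 0.2 < 0.10

    def test_already_optimal_is_fixed_point(self):
        model = SubstitutionModel.named("LG")
        tree = parse_newick("(A:0.15,B:0.15);")
        aln = simulate_alignment(tree, model, 3000, seed=9)
        once, lnl1 = optimize_branch_lengths(aln, tree, model, tol=1e-8)
        twice, lnl2 = optimize_branch_lengths(aln, once, model, tol=1e-8)
        assert lnl2 >= lnl1
        moved = [
            abs(a.length - b.length)
            for a, b in zip(once.root.postorder(), twice.root.postorder())
            if a.parent is not None
        ]
        assert max(moved) < 1e-4

    def test_never_decreases_lnl_and_multistart_consistency(self, lg_model):
        tree = parse_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        aln = simulate_alignment(tree, lg_model, 800, seed=21)
        start_lnl = tree_log_likelihood(aln, tree, lg_model)
        from_truth, lnl_truth = optimize_branch_lengths(aln, tree, lg_model)
        assert lnl_truth >= start_lnl
        perturbed = tree.copy()
        for n in perturbed.root.postorder():
            if n.parent is not None:
                n.length *= 4.0
        _, lnl_pert = optimize_branch_lengths(aln, perturbed, lg_model)
        assert abs(lnl_pert - lnl_truth) < 1e-3

    def test_non_finite_start_raises(self):
        model = SubstitutionModel.poisson(BINARY)
        tree = parse_newick("(A:0.0,B:0.0);")
        aln = Alignment(["A", "B"], np.array([["0"], ["1"]]), BINARY)
        with pytest.raises(OptimizationError):
            optimize_branch_lengths(aln, tree, model)


def test_simulation_inference_round_trip():
    """Gamma shape and total tree length are recovered within 15% relative
    error from a 10,000-site quartet simulation (fixed seed).  Shape and
    lengths are fitted by alternating coordinate optimization; a quartet
    (rather than a pair) is used because among-site rate variation is
    poorly identified from pairwise data alone."""
    true_alpha = 0.6
    model = SubstitutionModel.named("LG", gamma_shape=true_alpha)
    tree = parse_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
    true_length = 1.0
    aln = simulate_alignment(tree, model, 10_000, seed=2024)
    start = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
    guess = model.with_gamma_shape(1.5)
    prev = None
    for _ in range(12):
        start, _ = optimize_branch_lengths(aln, start, guess, tol=1e-6)
        guess, lnl = optimize_gamma_shape(aln, start, guess)
        if prev is not None and lnl - prev < 1e-4:
            break
        prev = lnl
    path = sum(n.length for n in start.root.postorder() if n.parent is not None)
    assert abs(path - true_length) / true_length < 0.15
    assert abs(guess.gamma_shape - true_alpha) / true_alpha < 0.15
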