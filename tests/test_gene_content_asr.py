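import numpy as np
import pytest

from helpers import enumeration_loglik, enumeration_marginal, random_tree

from magevo import (
    GainLossRates,
    Mk2Model,
    call_states,
    count_gains_losses,
    fit_rates,
    marginal_states,
    pruning_loglik,
    simulate_gene_content,
    simulate_yule_tree,
    transition_matrix,
    ultrametricize,
)
from magevo.gene_content_asr import stationary_prior
from magevo.io_core import BinaryContentMatrix, parse_newick


class TestUltrametricize:
    def test_already_ultrametric_is_fixed_point(self):
        tree = simulate_yule_tree(10, 1.0, seed=50)
        dated = ultrametricize(tree)
        for before, after in zip(tree.preorder(), dated.preorder()):
            assert after.length == pytest.approx(before.length, abs=1e-9)

    def test_hand_computed_mean_path_ages(self):
        dated = ultrametricize(parse_newick("((A:1,B:3):1,C:4);"))
        ages = {n.label: n.age for n in dated.preorder()}
        assert ages["n1"] == pytest.approx(2.0)
        assert ages["n0"] == pytest.approx(10 / 3)
        lengths = {n.label: n.length for n in dated.preorder() if n.parent}
        assert lengths["n1"] == pytest.approx(4 / 3)
        assert lengths["A"] == pytest.approx(2.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(10 / 3)

    def test_output_is_ultrametric_and_topology_preserved(self):
        rng = np.random.default_rng(51)
        for _ in range(10):
            tree = random_tree(rng, 7)
            dated = ultrametricize(tree)
            depths = [dated.depth(t) for t in dated.tips()]
            assert max(depths) - min(depths) < 1e-9
            strip = lambda t: t.to_newick().replace(
                ":", " ").translate(str.maketrans("", "", "0123456789. "))
            assert strip(dated) == strip(tree)

    def test_child_never_older_than_parent(self):
        dated = ultrametricize(parse_newick("((A:5,B:0.1):0.1,C:0.2);"))
        for node in dated.preorder():
            if node.parent is not None:
                assert node.length >= 0


class TestTransitionMatrix:
    def test_identity_at_zero(self):
        assert np.allclose(transition_matrix(GainLossRates(2, 1), 0.0), np.eye(2))

    def test_stationary_limit(self):
        P = transition_matrix(GainLossRates(1, 1), 1e6)
        assert np.allclose(P, 0.5)

    def test_closed_form_value(self):
        P = transition_matrix(GainLossRates(2, 1), 0.5)
        assert P[0, 1] == pytest.approx((2 / 3) * (1 - np.exp(-1.5)), abs=1e-12)

    def test_matches_matrix_exponential(self):
        from scipy.linalg import expm
        rates = GainLossRates(0.7, 1.9)
        Q = np.array([[-rates.q01, rates.q01], [rates.q10, -rates.q10]])
        for t in (0.1, 0.8, 3.0):
            assert np.allclose(transition_matrix(rates, t), expm(Q * t), atol=1e-12)

    def test_rows_are_distributions(self):
        P = transition_matrix(GainLossRates(0.3, 0.9), 0.7)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(GainLossRates(1, 1), -0.1)


class TestPruningLoglik:
    def test_single_tip_tree(self):
        tree = parse_newick("A:1;")
        matrix = BinaryContentMatrix.from_arrays(["A"], ["OG0"], [[1]])
        model = Mk2Model(GainLossRates(1, 1), (0.5, 0.5))
        total, per_og = pruning_loglik(tree, matrix, model)
        assert total == pytest.approx(np.log(0.5))

    def test_star_tree_zero_branches(self):
        tree = parse_newick("(A:0,B:0,C:0);")
        matrix = BinaryContentMatrix.from_arrays(
            ["A", "B", "C"], ["OG0"], [[1], [1], [1]])
        model = Mk2Model(GainLossRates(0.4, 1.1), stationary_prior(GainLossRates(0.4, 1.1)))
        total, _ = pruning_loglik(tree, matrix, model)
        assert total == pytest.approx(np.log(model.root_prior[1]))

    def test_matches_enumeration(self, four_tip_tree, four_tip_matrix):
        model = Mk2Model(GainLossRates(0.4, 1.1), (0.35, 0.65))
        _, per_og = pruning_loglik(four_tip_tree, four_tip_matrix, model)
        oracle = enumeration_loglik(four_tip_tree, four_tip_matrix, model)
        assert np.allclose(per_og, oracle, atol=1e-10)

    def test_matches_enumeration_on_random_trees(self):
        rng = np.random.default_rng(52)
        for _ in range(25):
            n_tips = int(rng.integers(2, 7))
            tree = random_tree(rng, n_tips)
            cells = rng.integers(0, 2, size=(n_tips, 5))
            matrix = BinaryContentMatrix.from_arrays(
                [t.label for t in tree.tips()], [f"OG{i}" for i in range(5)], cells)
            rates = GainLossRates(float(rng.uniform(0.05, 3)), float(rng.uniform(0.05, 3)))
            model = Mk2Model(rates, stationary_prior(rates))
            _, per_og = pruning_loglik(tree, matrix, model)
            assert np.allclose(per_og, enumeration_loglik(tree, matrix, model), atol=1e-9)

    def test_invariant_under_taxon_reordering(self, four_tip_tree, four_tip_matrix):
        model = Mk2Model(GainLossRates(0.4, 1.1), (0.5, 0.5))
        total, _ = pruning_loglik(four_tip_tree, four_tip_matrix, model)
        shuffled = BinaryContentMatrix(four_tip_matrix.frame.loc[["D", "B", "A", "C"]])
        total2, _ = pruning_loglik(four_tip_tree, shuffled, model)
        assert total2 == pytest.approx(total, abs=1e-10)

    def test_taxa_mismatch_lists_offenders(self, four_tip_tree):
        matrix = BinaryContentMatrix.from_arrays(["A", "B", "C", "E"], ["OG0"],
                                                 [[1], [0], [1], [0]])
        with pytest.raises(ValueError, match="E"):
            pruning_loglik(four_tip_tree, matrix, Mk2Model(GainLossRates(1, 1), (0.5, 0.5)))


class TestMarginalStates:
    def test_tips_reproduce_observations(self, four_tip_tree, four_tip_matrix):
        model = Mk2Model(GainLossRates(0.4, 1.1), (0.5, 0.5))
        recon = marginal_states(four_tip_tree, four_tip_matrix, model)
        for taxon in four_tip_matrix.taxon_ids:
            observed = four_tip_matrix.frame.loc[taxon].to_numpy()
            assert np.array_equal(recon.marginal_p1[taxon], observed.astype(float))

    def test_matches_brute_force_posterior(self, four_tip_tree, four_tip_matrix):
        model = Mk2Model(GainLossRates(0.4, 1.1), (0.3, 0.7))
        recon = marginal_states(four_tip_tree, four_tip_matrix, model)
        for label in ("R", "X", "Y"):
            oracle = enumeration_marginal(four_tip_tree, four_tip_matrix, model, label)
            assert np.allclose(recon.marginal_p1[label], oracle, atol=1e-10)

    def test_root_marginal_near_one_when_all_present_low_rates(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        matrix = BinaryContentMatrix.from_arrays(
            ["A", "B", "C", "D"], ["OG0"], [[1]] * 4)
        model = Mk2Model(GainLossRates(1e-4, 1e-4), (0.5, 0.5))
        recon = marginal_states(tree, matrix, model)
        assert recon.marginal_p1[tree.root.label][0] > 0.99


class TestCallStates:
    def _recon(self, p1_values, tree, matrix):
        model = Mk2Model(GainLossRates(0.4, 1.1), (0.5, 0.5))
        recon = marginal_states(tree, matrix, model)
        for label, value in p1_values.items():
            recon.marginal_p1[label] = np.array([value])
        return recon

    def test_threshold_and_tie_rule(self, four_tip_tree):
        matrix = BinaryContentMatrix.from_arrays(
            ["A", "B", "C", "D"], ["OG0"], [[1], [0], [1], [0]])
        recon = self._recon({"X": 0.6, "Y": 0.4, "R": 0.5}, four_tip_tree, matrix)
        calls = call_states(recon, four_tip_tree, matrix)
        assert calls["X"][0] == 1
        assert calls["Y"][0] == 0
        assert calls["R"][0] == 0  # exactly at the threshold calls absent

    def test_tips_keep_observed_states(self, four_tip_tree):
        matrix = BinaryContentMatrix.from_arrays(
            ["A", "B", "C", "D"], ["OG0"], [[1], [0], [1], [0]])
        recon = self._recon({}, four_tip_tree, matrix)
        calls = call_states(recon, four_tip_tree, matrix)
        assert calls["A"][0] == 1 and calls["B"][0] == 0


class TestCountGainsLosses:
    def test_no_changes_no_events(self, four_tip_tree):
        calls = {n.label: np.ones(3, dtype=np.int8) for n in four_tip_tree.preorder()}
        summary = count_gains_losses(calls, four_tip_tree)
        assert summary.total_gains == 0 and summary.total_losses == 0

    def test_single_gain_on_branch(self, four_tip_tree):
        calls = {n.label: np.zeros(1, dtype=np.int8) for n in four_tip_tree.preorder()}
        calls["X"] = np.ones(1, dtype=np.int8)
        summary = count_gains_losses(calls, four_tip_tree)
        assert summary.per_branch["X"] == (1, 0)
        # the branches below X see X=1 -> child 0: losses
        assert summary.per_branch["A"] == (0, 1)

    def test_bounded_by_parent_state_counts(self, four_tip_tree):
        rng = np.random.default_rng(53)
        calls = {n.label: rng.integers(0, 2, size=20).astype(np.int8)
                 for n in four_tip_tree.preorder()}
        summary = count_gains_losses(calls, four_tip_tree)
        for node in four_tip_tree.preorder():
            if node.parent is None:
                continue
            gains, losses = summary.per_branch[node.label]
            assert gains <= (calls[node.parent.label] == 0).sum()
            assert losses <= (calls[node.parent.label] == 1).sum()


class TestFitRates:
    def test_recovery_small(self):
        tree = simulate_yule_tree(48, 1.0, seed=54)
        matrix, _ = simulate_gene_content(tree, 800, GainLossRates(0.3, 0.9), 0.25, 55)
        model = fit_rates(tree, matrix)
        assert model.rates.q01 == pytest.approx(0.3, rel=0.35)
        assert model.rates.q10 == pytest.approx(0.9, rel=0.35)

    def test_state_relabeling_swaps_rates(self):
        tree = simulate_yule_tree(24, 1.0, seed=56)
        matrix, _ = simulate_gene_content(tree, 400, GainLossRates(0.4, 1.0), 0.3, 57)
        model = fit_rates(tree, matrix)
        flipped = BinaryContentMatrix(1 - matrix.frame)
        model_flipped = fit_rates(tree, flipped)
        assert model_flipped.rates.q01 == pytest.approx(model.rates.q10, rel=0.05)
        assert model_flipped.rates.q10 == pytest.approx(model.rates.q01, rel=0.05)

    def test_constant_matrix_warns_boundary(self):
        tree = simulate_yule_tree(8, 1.0, seed=58)
        matrix = BinaryContentMatrix.from_arrays(
            [t.label for t in tree.tips()], ["OG0", "OG1"], np.ones((8, 2), dtype=int))
        with pytest.warns(UserWarning, match="boundary"):
            model = fit_rates(tree, matrix)
        assert model.rates.q10 <= 1e-3

    def test_equal_rates_mode(self):
        tree = simulate_yule_tree(16, 1.0, seed=59)
        matrix, _ = simulate_gene_content(tree, 300, GainLossRates(0.5, 0.5), 0.5, 60)
        model = fit_rates(tree, matrix, equal_rates=True)
        assert model.rates.q01 == model.rates.q10
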