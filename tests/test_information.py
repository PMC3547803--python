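"""Information-engine tests: combination probabilities, mutual information,
marginal decomposition, class assignment, expected bins, aggregation."""

import numpy as np
import pytest

from adema import (
    MetaboliteSubset,
    aggregate_expected_levels,
    classify_combination,
    combination_probability_individual,
    combination_probability_population,
    enumerate_combinations,
    figure_example,
    fit_subset_model,
    marginal_information,
    subset_mutual_information,
)
from adema.binning import BinnedCohort, bin_cohort
from adema.information import (
    SubsetModel,
    expected_bins_from_weights,
    round_half_away,
)
from oracles import full_engine_reference, mutual_information_entropy_route


def _hard_binned(bins, M):
    """BinnedCohort with unit mass on the given 1-based bins.

    bins : (n_samples, d) integer array
    """
    bins = np.asarray(bins)
    n, d = bins.shape
    probs = np.zeros((n, d, M))
    for s in range(n):
        for j in range(d):
            probs[s, j, bins[s, j] - 1] = 1.0
    ranges = np.tile([0.0, 1.0], (d, 1))
    return BinnedCohort(probs=probs, ranges=ranges, M=M, k=1)


def _index(d):
    return {f"m{j + 1}": j for j in range(d)}


def _subset(d):
    return MetaboliteSubset(tuple(f"m{j + 1}" for j in range(d)))


class TestCombinationProbabilities:
    def test_hard_bins_are_indicator(self):
        binned = _hard_binned([[2, 3]], M=3)
        sub, idx = _subset(2), _index(2)
        assert combination_probability_individual(binned, 0, idx, sub, (2, 3)) == 1.0
        assert combination_probability_individual(binned, 0, idx, sub, (2, 2)) == 0.0

    def test_product_rule(self):
        probs = np.full((1, 2, 2), 0.5)
        binned = BinnedCohort(probs=probs, ranges=np.tile([0.0, 1.0], (2, 1)), M=2, k=2)
        sub, idx = _subset(2), _index(2)
        for o in [(1, 1), (1, 2), (2, 1), (2, 2)]:
            assert combination_probability_individual(binned, 0, idx, sub, o) == 0.25

    def test_population_mean_and_normalization(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(3), size=(5, 2))
        binned = BinnedCohort(probs=probs, ranges=np.tile([0.0, 1.0], (2, 1)), M=3, k=3)
        sub, idx = _subset(2), _index(2)
        total = sum(
            combination_probability_population(binned, idx, sub, o)
            for o in enumerate_combinations(3, 2)
        )
        assert total == pytest.approx(1.0, abs=1e-12)
        # single-sample population mean equals the individual probability
        one = BinnedCohort(probs=probs[:1], ranges=binned.ranges, M=3, k=3)
        assert combination_probability_population(one, idx, sub, (2, 1)) == pytest.approx(
            combination_probability_individual(one, 0, idx, sub, (2, 1))
        )

    def test_empty_filter_rejected(self):
        binned = _hard_binned([[1], [2]], M=2)
        with pytest.raises(ValueError):
            combination_probability_population(
                binned, _index(1), _subset(1), (1,), sample_mask=[False, False]
            )


class TestMutualInformation:
    def test_perfect_separation_balanced_classes_is_one_bit(self):
        binned = _hard_binned([[1], [1], [2], [2]], M=2)
        labels = np.array(["control", "control", "variable", "variable"])
        I = subset_mutual_information(binned, labels, _index(1), _subset(1))
        assert I == pytest.approx(1.0)

    def test_class_independent_bins_give_zero(self):
        binned = _hard_binned([[1], [2], [1], [2]], M=2)
        labels = np.array(["control", "control", "variable", "variable"])
        I = subset_mutual_information(binned, labels, _index(1), _subset(1))
        assert I == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_entropy_route_oracle(self, seed, make_random_binned):
        rng = np.random.default_rng(seed)
        n, d, M = 6, 2, 3
        binned, labels = make_random_binned(rng, n, d, M)
        I = subset_mutual_information(binned, labels, _index(d), _subset(d))
        ref = mutual_information_entropy_route(
            binned.probs, labels == "control", M
        )
        assert I == pytest.approx(ref, abs=1e-9)

    def test_bounded_by_class_entropy(self, make_random_binned):
        rng = np.random.default_rng(99)
        for _ in range(10):
            binned, labels = make_random_binned(rng, 8, 2, 3)
            I = subset_mutual_information(binned, labels, _index(2), _subset(2))
            p = (labels == "control").mean()
            H_C = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
            assert -1e-12 <= I <= H_C + 1e-9


class TestMarginalInformation:
    def test_decomposition_and_nonnegativity(self, make_random_binned):
        rng = np.random.default_rng(17)
        for _ in range(20):
            binned, labels = make_random_binned(rng, 7, 2, 3)
            model = fit_subset_model(binned, labels, _index(2), _subset(2))
            assert model.mi.sum() == pytest.approx(model.I, abs=1e-6)
            assert (model.mi >= -1e-12).all()

    def test_equal_conditionals_zero_marginal(self):
        binned = _hard_binned([[1], [2], [1], [2]], M=2)
        labels = np.array(["control", "control", "variable", "variable"])
        stat = marginal_information(binned, labels, _index(1), _subset(1), (1,))
        assert stat.term_control == pytest.approx(0.0, abs=1e-12)
        assert stat.term_variable == pytest.approx(0.0, abs=1e-12)
        assert stat.mi_o == pytest.approx(0.0, abs=1e-12)

    def test_one_positive_term_forces_other_below(self, make_random_binned):
        """Over-representation in one class implies under-representation in the
        other: whenever a class term is positive the opposing term is smaller."""
        rng = np.random.default_rng(23)
        for _ in range(30):
            binned, labels = make_random_binned(rng, 8, 2, 3)
            model = fit_subset_model(binned, labels, _index(2), _subset(2))
            pos_v = model.term_variable > 0
            assert (model.term_control[pos_v] < model.term_variable[pos_v]).all()
            pos_c = model.term_control > 0
            assert (model.term_variable[pos_c] < model.term_control[pos_c]).all()


class TestClassifyCombination:
    def test_variable_only_combination_assigned_variable(self):
        binned = _hard_binned([[1], [2]], M=2)
        labels = np.array(["control", "variable"])
        stat = marginal_information(binned, labels, _index(1), _subset(1), (2,))
        assert stat.term_variable > 0
        assert classify_combination(stat) == "variable"

    def test_tie_goes_to_control(self):
        binned = _hard_binned([[1], [1]], M=2)
        labels = np.array(["control", "variable"])
        stat = marginal_information(binned, labels, _index(1), _subset(1), (1,))
        assert stat.term_control == stat.term_variable
        assert classify_combination(stat) == "control"


class TestExpectedBins:
    def test_single_combination_returned_verbatim(self):
        combos = np.array([[2, 4, 1]])
        assert expected_bins_from_weights(combos, np.array([1.0])).tolist() == [2, 4, 1]

    def test_weighted_rounding_half_away(self):
        combos = np.array([[2], [4]])
        weights = np.array([0.75, 0.25])  # 2.5 -> 3 under half-away rounding
        assert expected_bins_from_weights(combos, weights).tolist() == [3]

    def test_round_half_away_convention(self):
        assert round_half_away([0.5, 1.5, 2.5, 2.4, -0.5]).tolist() == [1, 2, 3, 2, -1]

    def test_degenerate_class_falls_back_to_midpoint(self):
        # both samples identical: no information, both classes degenerate
        binned = _hard_binned([[2, 2], [2, 2]], M=3)
        labels = np.array(["control", "variable"])
        model = fit_subset_model(binned, labels, _index(2), _subset(2))
        assert model.I == pytest.approx(0.0, abs=1e-12)
        assert model.degenerate == {"control": True, "variable": True}
        assert model.expected_bins["control"].tolist() == [2, 2]  # round((3+1)/2)


class TestFullEngineOracle:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("d,M,n", [(1, 2, 4), (2, 3, 6), (3, 3, 8), (3, 2, 5)])
    def test_every_quantity_matches_enumeration(self, seed, d, M, n, make_random_binned):
        rng = np.random.default_rng(1000 * seed + 7 * d + M + n)
        binned, labels = make_random_binned(rng, n, d, M)
        model = fit_subset_model(binned, labels, _index(d), _subset(d))
        ref = full_engine_reference(binned.probs, labels == "control", M)
        assert [tuple(c) for c in model.combos] == ref["combos"]
        for key, ours in [
            ("p_o", model.p_o),
            ("p_o_control", model.p_o_control),
            ("p_o_variable", model.p_o_variable),
            ("term_control", model.term_control),
            ("term_variable", model.term_variable),
            ("mi", model.mi),
        ]:
            assert np.allclose(ours, ref[key], atol=1e-9), key
        assert model.I == pytest.approx(ref["I"], abs=1e-9)
        assert model.assigned.tolist() == ref["assigned"]
        for cls in ("control", "variable"):
            assert tuple(model.expected_bins[cls]) == ref["expected_bins"][cls]

    def test_all_combinations_enumerated(self, make_random_binned):
        rng = np.random.default_rng(5)
        binned, labels = make_random_binned(rng, 5, 3, 3)
        model = fit_subset_model(binned, labels, _index(3), _subset(3))
        assert len(model.combos) == 3**3
        assert len({tuple(c) for c in model.combos}) == 3**3


class TestAggregation:
    @staticmethod
    def _stub_model(members, I, control_bins, variable_bins, M=6):
        d = len(members)
        size = M**d
        return SubsetModel(
            subset=MetaboliteSubset(tuple(members)),
            M=M,
            combos=enumerate_combinations(M, d),
            mi=np.zeros(size), term_control=np.zeros(size),
            term_variable=np.zeros(size),
            p_o=np.zeros(size), p_o_control=np.zeros(size),
            p_o_variable=np.zeros(size),
            assigned=np.full(size, "control", dtype=object),
            I=I,
            expected_bins={
                "control": np.asarray(control_bins),
                "variable": np.asarray(variable_bins),
            },
        )

    def test_single_subset_passthrough(self):
        m = self._stub_model(["a", "b"], I=0.4, control_bins=[2, 3], variable_bins=[5, 1])
        levels = aggregate_expected_levels([m], ["a", "b"])
        assert levels.control_bins == {"a": 2, "b": 3}
        assert levels.variable_bins == {"a": 5, "b": 1}
        assert levels.delta("a") == 3 and levels.direction("a") == "increase"
        assert levels.delta("b") == -2 and levels.direction("b") == "decrease"

    def test_agreeing_subsets_preserve_bin(self):
        m1 = self._stub_model(["a"], I=0.7, control_bins=[4], variable_bins=[4])
        m2 = self._stub_model(["a"], I=0.1, control_bins=[4], variable_bins=[4])
        levels = aggregate_expected_levels([m1, m2], ["a"])
        assert levels.control_bins["a"] == 4
        assert levels.direction("a") == "no-change"

    def test_information_weighted_average(self):
        m1 = self._stub_model(["a"], I=0.3, control_bins=[2], variable_bins=[2])
        m2 = self._stub_model(["a"], I=0.1, control_bins=[4], variable_bins=[4])
        levels = aggregate_expected_levels([m1, m2], ["a"])
        # 0.75 * 2 + 0.25 * 4 = 2.5 -> 3 under half-away rounding
        assert levels.control_bins["a"] == 3

    def test_uncovered_metabolite_flagged(self):
        m = self._stub_model(["a"], I=0.2, control_bins=[1], variable_bins=[2])
        levels = aggregate_expected_levels([m], ["a", "zzz"])
        assert levels.uncovered == ["zzz"]
        assert "zzz" not in levels.control_bins


class TestWorkedExample:
    def test_four_combinations_and_documented_expectations(self):
        cohort, subsets, expected = figure_example()
        binned = bin_cohort(cohort.values, expected["M"], expected["k"])
        index = {m: j for j, m in enumerate(cohort.metabolite_ids)}
        model = fit_subset_model(binned, cohort.labels, index, subsets[0])
        assert len(model.combos) == expected["n_combinations"] == 4
        assert tuple(model.expected_bins["variable"]) == expected["variable_bins"] == (2, 2)
        assert tuple(model.expected_bins["control"]) == expected["control_bins"] == (1, 1)
        # the up/up combination is the variable signature
        idx_upup = int(np.flatnonzero((model.combos == (2, 2)).all(axis=1))[0])
        assert model.assigned[idx_upup] == "variable"
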