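"""Fitness terms: MAE, waste, mismatch, entropy, coverage, parsimony, composite."""

import numpy as np
import pytest

from counteract import (
    Combination,
    CostTable,
    EffectMatrix,
    FitnessWeights,
    composite_fitness,
    coverage_reward,
    entropy_penalty,
    mae,
    mismatch_penalty,
    proportional_attribution,
    usage_count_cost,
    waste_penalty,
)
from counteract.attribution import ContributionMatrix


def _contrib(c, values):
    values = np.asarray(values, dtype=float)
    return ContributionMatrix(
        genes=tuple(f"G{i}" for i in range(values.shape[0])),
        drugs=tuple(f"d{j}" for j in range(values.shape[1])),
        values=values,
        effect=np.clip(values.sum(axis=1), -1, 1),
        method="proportional",
    )


class TestMAE:
    def test_perfect_match_is_zero(self):
        c = np.array([-1.0, 1.0])
        assert mae(c, c) == 0.0

    def test_null_effect(self):
        assert mae(np.array([-1.0, 1.0]), np.zeros(2)) == 1.0

    def test_maximal_deviation(self):
        assert mae(np.array([-1.0]), np.array([1.0])) == 2.0

    def test_mask_restricts_to_scenario_genes(self):
        c = np.array([1.0, 0.0, -1.0])
        e = np.array([1.0, 0.9, 0.0])  # off-target gene ignored
        assert mae(c, e) == pytest.approx(0.5)

    def test_empty_mask_is_error(self):
        with pytest.raises(ValueError):
            mae(np.zeros(3), np.zeros(3))


class TestWaste:
    def test_exact_fulfillment_no_overshoot(self):
        c = np.array([1.0])
        assert waste_penalty(c, _contrib(c, [[0.6, 0.4]])) == 0.0

    def test_overshoot_down_direction(self):
        c = np.array([-1.0])
        assert waste_penalty(c, _contrib(c, [[-0.8, -0.5]])) == pytest.approx(0.3)

    def test_opposite_credits_do_not_waste(self):
        c = np.array([1.0])
        assert waste_penalty(c, _contrib(c, [[-0.7, -0.9]])) == 0.0


class TestMismatch:
    def test_aligned_credits_zero(self):
        c = np.array([1.0, -1.0])
        assert mismatch_penalty(c, _contrib(c, [[0.5, 0.5], [-0.3, -0.2]])) == 0.0

    def test_opposing_magnitudes_summed(self):
        c = np.array([1.0])
        assert mismatch_penalty(c, _contrib(c, [[0.6, -0.2]])) == pytest.approx(0.2)

    def test_masked_genes_contribute_nothing(self):
        c = np.array([1.0, 0.0])
        assert mismatch_penalty(c, _contrib(c, [[0.6, 0.0], [-0.9, -0.9]])) == 0.0

    def test_monotone_in_opposing_magnitude(self):
        c = np.array([1.0])
        low = mismatch_penalty(c, _contrib(c, [[0.6, -0.1]]))
        high = mismatch_penalty(c, _contrib(c, [[0.6, -0.4]]))
        assert high >= low


class TestEntropy:
    def test_single_contributor_zero(self):
        c = np.array([1.0])
        assert entropy_penalty(c, _contrib(c, [[0.7, 0.0]])) == 0.0

    @pytest.mark.parametrize("n", [2, 3])
    def test_equal_contributors_ln_n(self, n):
        c = np.array([1.0])
        values = [[0.3] * n]
        assert entropy_penalty(c, _contrib(c, values)) == pytest.approx(np.log(n))

    def test_opposing_credit_excluded_from_shares(self):
        c = np.array([1.0])
        # only one same-sign contributor -> H = 0 despite the opposing credit
        assert entropy_penalty(c, _contrib(c, [[0.7, -0.3]])) == 0.0


class TestCoverage:
    def test_all_targets_met(self):
        c = np.array([1.0, -1.0])
        cov = coverage_reward(c, _contrib(c, [[1.0, 0.0], [0.0, -1.0]]))
        assert cov == pytest.approx(2.0)

    def test_partial_fulfillment(self):
        c = np.array([-1.0])
        assert coverage_reward(c, _contrib(c, [[-0.5, 0.0]])) == pytest.approx(0.5)

    def test_overshoot_capped_at_target(self):
        c = np.array([1.0])
        assert coverage_reward(c, _contrib(c, [[0.9, 0.8]])) == pytest.approx(1.0)

    def test_omega_weights_and_normalization(self):
        c = np.array([1.0, 1.0])
        contrib = _contrib(c, [[1.0, 0.0], [0.0, 0.0]])
        assert coverage_reward(c, contrib, omega=np.array([2.0, 1.0])) == pytest.approx(2.0)
        assert coverage_reward(c, contrib, omega=np.array([2.0, 1.0]),
                               normalize=True) == pytest.approx(2.0 / 3.0)


class TestUsageCountCost:
    def test_null_player_excluded(self):
        contrib = _contrib(np.array([1.0, 1.0]), [[0.5, 0.0], [0.4, 0.0]])
        phi, count, cost = usage_count_cost(contrib)
        np.testing.assert_allclose(phi, [0.9, 0.0])
        assert count == 1 and cost == 0.0

    def test_zero_cost_table_counts_actives(self):
        contrib = _contrib(np.array([1.0]), [[0.2, 0.3, 0.1]])
        _, count, cost = usage_count_cost(contrib)
        assert count == 3 and cost == 0.0

    def test_negative_cost_prefers_drug(self):
        contrib = _contrib(np.array([1.0]), [[0.2, 0.3]])
        _, _, cost = usage_count_cost(contrib, CostTable({"d0": -0.5, "d1": 1.0}))
        assert cost == pytest.approx(0.5)

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            usage_count_cost(_contrib(np.array([1.0]), [[0.5]]), epsilon=0.0)


class TestComposite:
    def test_mae_only_weights_reduce_to_mae(self, toy_effects, toy_scenario):
        from counteract import vectorize

        c = vectorize(toy_scenario, toy_effects.genes)
        combo = Combination(["d1", "d3"])
        bd = composite_fitness(c, toy_effects, combo, weights=FitnessWeights.mae_only())
        assert bd.composite_j == pytest.approx(bd.mae)

    def test_perfect_planted_combination_terms(self, planted):
        from counteract import vectorize

        scenario, effects, planted_drugs = planted
        c = vectorize(scenario, effects.genes)
        combo = Combination(planted_drugs, max_drugs=3)
        w = FitnessWeights()
        bd = composite_fitness(c, effects, combo, weights=w)
        assert bd.mae == 0.0
        assert bd.r_waste == 0.0
        assert bd.r_mismatch == 0.0
        assert bd.coverage == pytest.approx(1.0)
        # J = -tau*1 + lambda*(k/K): only count and coverage terms remain
        expected = -w.tau + w.lambda_count * (len(planted_drugs) / 3)
        assert bd.composite_j == pytest.approx(expected)

    def test_null_player_changes_nothing(self, planted):
        from counteract import vectorize

        scenario, effects, planted_drugs = planted
        assert "null1" in effects.drugs
        c = vectorize(scenario, effects.genes)
        base = composite_fitness(c, effects, Combination(planted_drugs, max_drugs=3))
        plus = composite_fitness(
            c, effects, Combination(list(planted_drugs) + ["null1"], max_drugs=3)
        )
        for term in ("mae", "r_waste", "r_mismatch", "r_entropy", "coverage", "r_count"):
            assert getattr(base, term) == pytest.approx(getattr(plus, term))

    def test_terms_invariant_to_slot_order(self, toy_effects, toy_scenario):
        from counteract import vectorize

        c = vectorize(toy_scenario, toy_effects.genes)
        a = composite_fitness(c, toy_effects, Combination(["d1", "d2", "d3"]))
        b = composite_fitness(c, toy_effects, Combination(["d3", "d1", "d2"]))
        assert a.as_dict() == pytest.approx(b.as_dict())

    def test_single_drug_waste_is_zero_everywhere(self, toy_effects, toy_scenario):
        from counteract import vectorize

        c = vectorize(toy_scenario, toy_effects.genes)
        for drug in toy_effects.drugs[:3]:
            bd = composite_fitness(c, toy_effects, Combination([drug]))
            assert bd.r_waste == 0.0  # clip keeps |e_g| <= 1, no overshoot possible


def test_weights_must_be_nonnegative():
    with pytest.raises(ValueError):
        FitnessWeights(alpha=-0.1)


def test_cost_table_from_file(tmp_path):
    path = tmp_path / "costs.tsv"
    path.write_text("drug_id\tcost\nDrugA\t1.5\ndrugb\t-0.5\n")
    table = CostTable.from_file(path)
    assert table.get("druga") == 1.5  # header skipped, ids lowercased
    assert table.get("DRUGB") == -0.5
    assert table.get("other") == 0.0
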