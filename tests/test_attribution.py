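"""Combination effects and credit attribution (proportional and Shapley).

The Shapley oracle here enumerates all drug orderings and averages marginal
contributions directly — an independent route from the package's
subset-enumeration implementation.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from counteract import (
    Combination,
    EffectMatrix,
    combination_effect,
    proportional_attribution,
    shapley_attribution,
)


def _matrix(values, drugs=None):
    values = np.asarray(values, dtype=float)
    genes = [f"G{i}" for i in range(values.shape[0])]
    drugs = drugs or [f"d{j}" for j in range(values.shape[1])]
    return EffectMatrix(genes, drugs, values)


def shapley_by_orderings(cols: np.ndarray) -> np.ndarray:
    """Oracle: average clipped-prefix marginals over every ordering."""
    G, k = cols.shape
    out = np.zeros_like(cols)
    orderings = list(itertools.permutations(range(k)))
    for order in orderings:
        prev = np.zeros(G)
        total = np.zeros(G)
        for j in order:
            total = total + cols[:, j]
            clipped = np.clip(total, -1, 1)
            out[:, j] += clipped - prev
            prev = clipped
    return out / len(orderings)


def test_combination_effect_sums_and_clips(toy_effects):
    e = combination_effect(toy_effects, Combination(["d1"]))
    np.testing.assert_allclose(e, [1.0, 0.7, -1.0])
    e = combination_effect(toy_effects, Combination(["d1", "d2"]))
    np.testing.assert_allclose(e, [1.0, 1.0, -1.0])  # GB: 0.7+0.8 clips to 1
    e = combination_effect(toy_effects, Combination(["d1", "d3"]))
    np.testing.assert_allclose(e, [0.5, 0.7, 0.0])   # GC: -1+1 cancels


def test_unknown_drug_is_fatal(toy_effects):
    with pytest.raises(KeyError):
        combination_effect(toy_effects, Combination(["nope"]))


def test_duplicate_slots_collapse(toy_effects):
    single = combination_effect(toy_effects, Combination(["d1"]))
    doubled = combination_effect(toy_effects, Combination(["d1", "d1", None]))
    np.testing.assert_allclose(single, doubled)


def test_proportional_attribution_hand_example():
    # one gene, raw effects 0.7 and 0.8: e = 1.0, shares 0.7/1.5 and 0.8/1.5
    m = _matrix([[0.7, 0.8]])
    a = proportional_attribution(m, Combination(["d0", "d1"]))
    np.testing.assert_allclose(a.values, [[0.7 / 1.5, 0.8 / 1.5]])
    assert a.values.sum() == pytest.approx(1.0)


def test_proportional_attribution_zero_sum_credits_nobody():
    m = _matrix([[0.5, -0.5]])
    a = proportional_attribution(m, Combination(["d0", "d1"]))
    np.testing.assert_array_equal(a.values, [[0.0, 0.0]])


def test_proportional_single_drug_equals_effect(toy_effects):
    a = proportional_attribution(toy_effects, Combination(["d2"]))
    np.testing.assert_allclose(a.values[:, 0], a.effect)


def test_shapley_two_identical_drugs_split_clipped_total():
    # both orderings: first gets 0.8, second gets 1.0-0.8=0.2 -> each 0.5
    m = _matrix([[0.8, 0.8]])
    phi = shapley_attribution(m, Combination(["d0", "d1"]), mode="exact")
    np.testing.assert_allclose(phi.values, [[0.5, 0.5]])


def test_shapley_additive_regime_returns_raw_effects():
    m = _matrix([[0.3, 0.4], [-0.2, 0.1]])
    phi = shapley_attribution(m, Combination(["d0", "d1"]), mode="exact")
    np.testing.assert_allclose(phi.values, m.values, atol=1e-12)


@pytest.mark.parametrize("k", [2, 3, 4])
def test_exact_shapley_matches_ordering_oracle(k):
    rng = np.random.default_rng(42 + k)
    for _ in range(20):
        cols = rng.uniform(-1, 1, size=(5, k))
        m = _matrix(cols)
        combo = Combination(m.drugs[:k], max_drugs=k)
        phi = shapley_attribution(m, combo, mode="exact")
        np.testing.assert_allclose(phi.values, shapley_by_orderings(cols), atol=1e-10)


def test_shapley_symmetry_and_null_player():
    rng = np.random.default_rng(7)
    col = rng.uniform(-1, 1, size=4)
    cols = np.column_stack([col, col, np.zeros(4), rng.uniform(-1, 1, 4)])
    m = _matrix(cols)
    phi = shapley_attribution(m, Combination(m.drugs, max_drugs=4), mode="exact")
    np.testing.assert_allclose(phi.values[:, 0], phi.values[:, 1], atol=1e-12)
    np.testing.assert_array_equal(phi.values[:, 2], np.zeros(4))


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_efficiency_property(seed):
    """sum_j a[g, j] equals the clipped net effect, both attribution routes."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 7))
    cols = rng.uniform(-1, 1, size=(6, k))
    m = _matrix(cols)
    combo = Combination(m.drugs, max_drugs=6)
    e = combination_effect(m, combo)
    prop = proportional_attribution(m, combo)
    np.testing.assert_allclose(prop.values.sum(axis=1), e, atol=1e-12)
    phi = shapley_attribution(m, combo, mode="exact")
    np.testing.assert_allclose(phi.values.sum(axis=1), e, atol=1e-10)


def test_monte_carlo_converges_to_exact():
    rng = np.random.default_rng(0)
    cols = rng.uniform(-1, 1, size=(6, 4))
    m = _matrix(cols)
    combo = Combination(m.drugs, max_drugs=4)
    exact = shapley_attribution(m, combo, mode="exact")
    mc = shapley_attribution(m, combo, mode="monte_carlo", permutations=256, seed=3)
    assert np.abs(mc.values - exact.values).max() < 0.35  # Hoeffding bound at 256 draws
    assert mc.permutations == 256


def test_monte_carlo_is_seeded_and_validates_permutations():
    m = _matrix([[0.5, 0.7, -0.3]])
    combo = Combination(m.drugs, max_drugs=3)
    a = shapley_attribution(m, combo, mode="monte_carlo", permutations=64, seed=5)
    b = shapley_attribution(m, combo, mode="monte_carlo", permutations=64, seed=5)
    np.testing.assert_array_equal(a.values, b.values)
    with pytest.raises(ValueError):
        shapley_attribution(m, combo, mode="monte_carlo", permutations=0)


def test_proportional_sign_preservation():
    rng = np.random.default_rng(11)
    cols = rng.uniform(-1, 1, size=(8, 3))
    m = _matrix(cols)
    combo = Combination(m.drugs, max_drugs=3)
    a = proportional_attribution(m, combo)
    raw_sum = cols.sum(axis=1)
    consistent = np.sign(a.effect) == np.sign(raw_sum)
    for g in np.nonzero(consistent & (raw_sum != 0))[0]:
        nz = cols[g] != 0
        assert np.all(np.sign(a.values[g, nz]) == np.sign(cols[g, nz]))
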