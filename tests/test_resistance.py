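import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecocorridor import (
    ClassificationTable,
    base_resistance,
    classify_factor,
    correct_resistance,
    entropy_weights,
    sensitivity_index,
)
from ecocorridor.grid import FactorStack
from ecocorridor.resistance import DEFAULT_CLASSIFICATION, DEFAULT_WEIGHTS

from conftest import grid


class TestClassifyFactor:
    def test_slope_interval(self):
        out = classify_factor(grid([[20.0, 5.0, 40.0]]),
                              DEFAULT_CLASSIFICATION["slope"])
        np.testing.assert_array_equal(out.values, [[30, 10, 80]])

    def test_land_cover_category(self):
        r = grid([[1.0, 8.0]])
        out = classify_factor(r, DEFAULT_CLASSIFICATION["land_cover"],
                              categories={1: "Forest land", 8: "Construction Land"})
        np.testing.assert_array_equal(out.values, [[5, 100]])

    def test_bedrock_category(self):
        out = classify_factor(grid([[4.0]]), DEFAULT_CLASSIFICATION["bedrock"],
                              categories={4: "Dolomite"})
        assert out.values[0, 0] == 70

    def test_interval_boundaries_left_closed(self):
        out = classify_factor(grid([[15.0, 25.0, 35.0]]),
                              DEFAULT_CLASSIFICATION["slope"])
        np.testing.assert_array_equal(out.values, [[30, 50, 80]])

    def test_unmapped_category_rejected(self):
        with pytest.raises(ValueError, match="unmapped"):
            classify_factor(grid([[9.0]]), DEFAULT_CLASSIFICATION["land_cover"],
                            categories={1: "Forest land"})

    def test_classified_coefficients_survive_identity_lookup(self):
        # re-classifying an already-classified raster through the identity
        # coefficient lookup changes nothing
        out = classify_factor(grid([[12.0, 28.0]]),
                              DEFAULT_CLASSIFICATION["soil_thickness"])
        identity = {c: c for c in (10, 40, 70)}
        again = classify_factor(out, identity)
        np.testing.assert_array_equal(again.values, out.values)


class TestEntropyWeights:
    def test_constant_column_gets_zero_weight(self):
        x = np.column_stack([np.full(50, 3.0), np.linspace(0, 1, 50)])
        w = entropy_weights(x)
        np.testing.assert_allclose(w, [0.0, 1.0], atol=1e-12)

    def test_proportional_columns_share_weight_equally(self):
        col = np.random.default_rng(0).random(100)
        w = entropy_weights(np.column_stack([col, 5.0 * col]))
        np.testing.assert_allclose(w, [0.5, 0.5], rtol=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_weights_nonnegative_and_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((20, 4)) * rng.integers(1, 100, size=4)
        w = entropy_weights(x)
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(), 1.0, rtol=1e-12)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="no information"):
            entropy_weights(np.ones((10, 3)))


class TestBaseResistance:
    def test_minimal_class_weighted_sum(self):
        # every factor in its minimal class under the default table:
        # 5*0.1671 + 10*(0.1198+0.2054+0.1436+0.1496+0.2145) = 9.1645
        coeffs = {"land_cover": 5.0, "slope": 10.0, "altitude": 10.0,
                  "vegetation_coverage": 10.0, "soil_thickness": 10.0,
                  "bedrock": 10.0}
        stack = FactorStack({k: grid([[v]]) for k, v in coeffs.items()})
        out = base_resistance(stack, DEFAULT_WEIGHTS)
        np.testing.assert_allclose(out.values, [[9.1645]], rtol=1e-12)

    def test_uniform_coefficients_are_fixed_point(self):
        stack = FactorStack({k: grid(np.full((2, 2), 100.0)) for k in DEFAULT_WEIGHTS})
        out = base_resistance(stack, DEFAULT_WEIGHTS)
        np.testing.assert_allclose(out.values, 100.0)

    def test_single_factor_identity(self):
        vals = np.array([[5.0, 30.0], [70.0, 100.0]])
        out = base_resistance(FactorStack({"only": grid(vals)}), {"only": 1.0})
        np.testing.assert_array_equal(out.values, vals)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(2)
        stack = FactorStack(
            {k: grid(rng.choice([5.0, 30.0, 80.0], size=(6, 6)))
             for k in DEFAULT_WEIGHTS}
        )
        out = base_resistance(stack, DEFAULT_WEIGHTS)
        assert out.values.min() >= 5.0 - 1e-9
        assert out.values.max() <= 80.0 + 1e-9


class TestSensitivityCorrection:
    def test_single_index_weight(self):
        stack = sensitivity_index(grid([[1.0, 0.0]]), grid([[0.0, 0.0]]),
                                  grid([[0.0, 0.0]]))
        np.testing.assert_allclose(stack.esi.values, [[0.483, 0.0]])

    def test_weights_sum_to_one_on_unit_indices(self):
        stack = sensitivity_index(grid([[1.0, 0.5]]), grid([[1.0, 0.5]]),
                                  grid([[1.0, 0.5]]))
        np.testing.assert_allclose(stack.esi.values, [[1.0, 0.5]])

    def test_constant_indices_flagged(self):
        stack = sensitivity_index(grid(np.zeros((2, 2))), grid(np.zeros((2, 2))),
                                  grid(np.zeros((2, 2))))
        assert stack.constant

    def test_uniform_sensitivity_is_noop(self):
        basic = grid(np.random.default_rng(0).random((4, 4)) * 50 + 10)
        stack = sensitivity_index(grid(np.full((4, 4), 0.3)),
                                  grid(np.full((4, 4), 0.3)),
                                  grid(np.full((4, 4), 0.3)))
        with pytest.warns(UserWarning, match="no-op"):
            surface = correct_resistance(basic, stack)
        np.testing.assert_array_equal(surface.corrected.values, basic.values)

    def test_ratio_to_mean_contract(self):
        # standardized sensitivity {0, 1}; a cell at 1 carries twice the
        # regional mean 0.5, so its resistance doubles
        basic = grid(np.full((1, 2), 10.0))
        stack = sensitivity_index(grid([[0.0, 1.0]]), grid([[0.0, 1.0]]),
                                  grid([[0.0, 1.0]]))
        surface = correct_resistance(basic, stack)
        np.testing.assert_allclose(surface.corrected.values, [[0.0, 20.0]])

    def test_scale_invariance_of_correction(self):
        rng = np.random.default_rng(7)
        basic = grid(rng.random((5, 5)) * 40 + 10)
        rdi, kci, sei = (rng.random((5, 5)) for _ in range(3))
        full = correct_resistance(
            basic, sensitivity_index(grid(rdi), grid(kci), grid(sei))
        )
        halved = correct_resistance(
            basic, sensitivity_index(grid(rdi / 2), grid(kci / 2), grid(sei / 2))
        )
        np.testing.assert_allclose(full.corrected.values, halved.corrected.values,
                                   rtol=1e-10)

    def test_mean_resistance_approximately_preserved(self):
        # uncorrelated R and sensitivity: ratio-to-mean keeps the mean R
        rng = np.random.default_rng(11)
        basic = grid(rng.random((60, 60)) * 50 + 10)
        stack = sensitivity_index(grid(rng.random((60, 60))),
                                  grid(rng.random((60, 60))),
                                  grid(rng.random((60, 60))))
        surface = correct_resistance(basic, stack)
        assert np.nanmean(surface.corrected.values) == pytest.approx(
            np.nanmean(basic.values), rel=0.05
        )

    def test_bad_weight_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sensitivity_index(grid([[0.5]]), grid([[0.5]]), grid([[0.5]]),
                              weights=(0.5, 0.4, 0.3))


def test_classification_table_weight_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        ClassificationTable(weights={"a": 0.5, "b": 0.3})
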