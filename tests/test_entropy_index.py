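"""Entropy-weight standardization, weighting, scoring, and level bands."""

import numpy as np
import pytest

from phsupply.entropy_index import (
    ScorePanel,
    StandardizedPanel,
    classify_quintiles,
    compose_score,
    entropy_weights,
    standardize,
)
from phsupply.panel_io import IndicatorPanel


def column_panel(values, direction=1):
    """One unit per row, one year, one indicator holding `values`."""
    vals = np.asarray(values, float).reshape(-1, 1, 1)
    units = tuple(f"u{i}" for i in range(len(values)))
    return IndicatorPanel(units, (2005,), ("i1",), (direction,), vals)


class TestStandardize:
    def test_benefit_direction(self):
        out = standardize(column_panel([2, 4, 6], 1))
        np.testing.assert_allclose(out.values.ravel(), [0, 0.5, 1])

    def test_cost_direction(self):
        out = standardize(column_panel([2, 4, 6], -1))
        np.testing.assert_allclose(out.values.ravel(), [1, 0.5, 0])

    def test_per_year_scope_reattains_unit_interval_each_year(self, rng):
        vals = rng.uniform(0, 10, size=(5, 3, 2))
        panel = IndicatorPanel(
            tuple("abcde"), (2005, 2006, 2007), ("i1", "i2"), (1, -1), vals
        )
        out = standardize(panel, scope="per-year")
        for t in range(3):
            for j in range(2):
                col = out.values[:, t, j]
                assert col.min() == pytest.approx(0.0, abs=1e-15)
                assert col.max() == pytest.approx(1.0, abs=1e-15)
        # independent recomputation oracle, straight from the min-max formulas
        for t in range(3):
            lo, hi = vals[:, t, 0].min(), vals[:, t, 0].max()
            np.testing.assert_allclose(
                out.values[:, t, 0], (vals[:, t, 0] - lo) / (hi - lo)
            )
            lo, hi = vals[:, t, 1].min(), vals[:, t, 1].max()
            np.testing.assert_allclose(
                out.values[:, t, 1], (hi - vals[:, t, 1]) / (hi - lo)
            )

    def test_constant_indicator_zeroed_with_warning(self):
        vals = np.array([[[1.0, 5.0]], [[2.0, 5.0]]])
        panel = IndicatorPanel(("u1", "u2"), (2005,), ("i1", "i2"), (1, 1), vals)
        with pytest.warns(UserWarning, match="i2"):
            out = standardize(panel)
        np.testing.assert_allclose(out.values[:, 0, 1], [0.0, 0.0])


class TestEntropyWeights:
    def std(self, matrix):
        m = np.asarray(matrix, float)
        units = tuple(f"u{i}" for i in range(m.shape[0]))
        inds = tuple(f"i{j}" for j in range(m.shape[1]))
        return StandardizedPanel(units, (2005,), inds, m[:, None, :])

    def test_identical_columns_share_weight(self):
        w = entropy_weights(self.std([[0.2, 0.2], [0.9, 0.9], [0.4, 0.4]]))
        np.testing.assert_allclose(w.weights, [0.5, 0.5])

    def test_uniform_column_gets_zero_weight(self):
        w = entropy_weights(self.std([[0.5, 0.1], [0.5, 0.9], [0.5, 0.3]]))
        assert w.entropy[0] == pytest.approx(1.0, abs=1e-12)
        assert w.redundancy[0] == 0.0
        assert w.weights[0] == 0.0
        assert w.weights[1] == 1.0

    def test_hand_calculated_oracle(self):
        # shares col1: [2/3, 0, 1/3]; col2: [0, 2/3, 1/3] (0*ln0 := 0)
        # e = -(1/ln 3)*(2/3 ln 2/3 + 1/3 ln 1/3) for both, so d equal, w = 1/2
        w = entropy_weights(self.std([[1, 0], [0, 1], [0.5, 0.5]]))
        e_expected = -(2 / 3 * np.log(2 / 3) + 1 / 3 * np.log(1 / 3)) / np.log(3)
        np.testing.assert_allclose(w.entropy, [e_expected, e_expected], atol=1e-14)
        np.testing.assert_allclose(w.weights, [0.5, 0.5], atol=1e-14)

    def test_all_constant_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            entropy_weights(self.std([[0.5, 0.2], [0.5, 0.2]]))

    def test_permutation_equivariance(self, rng):
        m = rng.uniform(size=(10, 4))
        w = entropy_weights(self.std(m))
        perm = [2, 0, 3, 1]
        w_perm = entropy_weights(self.std(m[:, perm]))
        np.testing.assert_allclose(w_perm.weights, w.weights[perm], atol=1e-12)

    def test_weights_sum_to_one(self, rng):
        m = rng.uniform(size=(30, 7))
        w = entropy_weights(self.std(m))
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestComposeScore:
    def make(self, std_vals, weights):
        m = np.asarray(std_vals, float)[:, None, :]
        units = tuple(f"u{i}" for i in range(m.shape[0]))
        inds = tuple(f"i{j}" for j in range(m.shape[2]))
        std = StandardizedPanel(units, (2005,), inds, m)
        wv = entropy_weights  # not used; build weights directly
        from phsupply.entropy_index import WeightVector

        w = np.asarray(weights, float)
        return std, WeightVector(inds, w, np.zeros_like(w), w.copy())

    @pytest.mark.parametrize(
        "std_row, weights, expected",
        [([1.0, 1.0], [0.5, 0.5], 1.0),
         ([0.0, 0.0], [0.5, 0.5], 0.0),
         ([1.0, 0.5], [0.3, 0.7], 0.65)],
    )
    def test_dot_product_examples(self, std_row, weights, expected):
        std, wv = self.make([std_row], weights)
        out = compose_score(std, wv)
        assert out.scores[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_indicator_mismatch_rejected(self):
        std, wv = self.make([[1.0, 0.5]], [0.3, 0.7])
        from phsupply.entropy_index import WeightVector

        bad = WeightVector(("other", "i1"), np.array([0.3, 0.7]),
                           np.zeros(2), np.array([0.3, 0.7]))
        with pytest.raises(ValueError):
            compose_score(std, bad)

    def test_benefit_monotonicity(self, rng):
        """Raising one standardized value never lowers that unit-year's score."""
        m = rng.uniform(size=(6, 3))
        std, wv = self.make(m, rng.dirichlet(np.ones(3)))
        base = compose_score(std, wv).scores[2, 0]
        m2 = m.copy()
        m2[2, 1] = min(1.0, m2[2, 1] + 0.2)
        std2, _ = self.make(m2, wv.weights)
        bumped = compose_score(std2, wv).scores[2, 0]
        assert bumped >= base


class TestQuintiles:
    BREAKS = (0.3235, 0.3862, 0.4489, 0.5116)

    def scores(self, values):
        v = np.asarray(values, float).reshape(-1, 1)
        return ScorePanel(tuple(f"u{i}" for i in range(len(values))), (2005,), v)

    def test_band_membership_with_explicit_breaks(self):
        out = classify_quintiles(self.scores([0.40, 0.45, 0.30, 0.55]), self.BREAKS)
        assert list(out["level"]) == ["medium", "upper-middle", "low", "high"]

    def test_boundary_score_falls_in_lower_band(self):
        out = classify_quintiles(self.scores([0.3862]), self.BREAKS)
        assert out["level"][0] == "lower-middle"

    def test_equal_scores_single_band(self):
        out = classify_quintiles(self.scores([0.4, 0.4, 0.4]))
        assert out["level"].nunique() == 1

    def test_matches_linear_scan_oracle(self, rng):
        vals = rng.uniform(size=40)
        out = classify_quintiles(self.scores(vals), self.BREAKS)
        from phsupply.entropy_index import QUINTILE_LABELS

        for v, lab in zip(vals, out["level"]):
            expected = QUINTILE_LABELS[sum(v > b for b in self.BREAKS)]
            assert lab == expected

    def test_nonmonotone_breaks_rejected(self):
        with pytest.raises(ValueError):
            classify_quintiles(self.scores([0.4]), (0.5, 0.4, 0.6, 0.7))
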