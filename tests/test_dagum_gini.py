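"""Dagum Gini decomposition: closed forms, brute-force oracle, invariants."""

import numpy as np
import pytest

from phsupply.dagum_gini import (
    gini_decompose,
    gini_overall,
    gini_series,
    relative_change_pct,
)
from phsupply.entropy_index import ScorePanel
from phsupply.panel_io import RegionPartition


class TestOverall:
    def test_equal_values_zero(self):
        assert gini_overall(np.full(5, 0.4)) == 0.0

    @pytest.mark.parametrize("c", [1.0, 0.37, 250.0])
    def test_two_point_closed_form(self, c):
        assert gini_overall(np.array([0.0, c])) == pytest.approx(0.5)

    def test_brute_force_pairwise_oracle(self, rng):
        x = rng.uniform(0.1, 1.0, size=21)
        direct = sum(abs(a - b) for a in x for b in x) / (2 * 21**2 * x.mean())
        assert gini_overall(x) == pytest.approx(direct, abs=1e-14)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            gini_overall(np.array([-1.0, 1.0]))


class TestDecompose:
    def test_disjoint_supports_have_no_transvariation(self, two_region_partition):
        d = gini_decompose(
            np.array([1.0, 2.0, 10.0, 11.0]),
            ("a1", "a2", "b1", "b2"), two_region_partition,
        )
        assert d.pair_affluence[("A", "B")] == pytest.approx(1.0)
        assert d.transvariation == pytest.approx(0.0, abs=1e-15)

    def test_single_occupied_group_is_all_within(self):
        part = RegionPartition.from_mapping({"a1": "A", "a2": "A"}, ("A", "B"))
        d = gini_decompose(np.array([1.0, 3.0]), ("a1", "a2"), part)
        assert d.within == pytest.approx(d.overall)
        assert d.between_net == 0.0 and d.transvariation == 0.0

    def test_brute_force_moment_oracle(self, two_region_partition):
        """Every component recomputed by exhaustive pair enumeration."""
        x = {"a1": 1.0, "a2": 3.0, "b1": 2.0, "b2": 4.0}
        ga, gb = [x["a1"], x["a2"]], [x["b1"], x["b2"]]
        d = gini_decompose(
            np.array([x["a1"], x["a2"], x["b1"], x["b2"]]),
            ("a1", "a2", "b1", "b2"), two_region_partition,
        )
        mean_a, mean_b, grand = np.mean(ga), np.mean(gb), 2.5
        g_aa = sum(abs(p - q) for p in ga for q in ga) / (2 * 4 * mean_a)
        g_bb = sum(abs(p - q) for p in gb for q in gb) / (2 * 4 * mean_b)
        g_ab = sum(abs(p - q) for p in ga for q in gb) / (4 * (mean_a + mean_b))
        pj, sj = 0.5, 2 * mean_a / (4 * grand)
        ph, sh = 0.5, 2 * mean_b / (4 * grand)
        # B higher mean: gross affluence & transvariation moments
        d_moment = np.mean([max(q - p, 0) for p in ga for q in gb])
        p_moment = np.mean([max(p - q, 0) for p in ga for q in gb])
        D = (d_moment - p_moment) / (d_moment + p_moment)
        g_w = g_aa * pj * sj + g_bb * ph * sh
        weight = pj * sh + ph * sj
        g_nb = g_ab * weight * D
        g_t = g_ab * weight * (1 - D)
        assert d.group_gini["A"] == pytest.approx(g_aa, abs=1e-14)
        assert d.group_gini["B"] == pytest.approx(g_bb, abs=1e-14)
        assert d.pair_gini[("A", "B")] == pytest.approx(g_ab, abs=1e-14)
        assert d.within == pytest.approx(g_w, abs=1e-14)
        assert d.between_net == pytest.approx(g_nb, abs=1e-14)
        assert d.transvariation == pytest.approx(g_t, abs=1e-14)
        assert d.overall == pytest.approx(g_w + g_nb + g_t, abs=1e-14)

    def test_additive_identity_and_nonnegativity_random(self, rng):
        """G = G_w + G_nb + G_t at 1e-10 over 1000 random partitions."""
        for _ in range(1000):
            n = rng.integers(6, 30)
            x = rng.uniform(0.05, 1.0, size=n)
            n_groups = rng.integers(2, 5)
            labels = rng.integers(0, n_groups, size=n)
            labels[:n_groups] = np.arange(n_groups)   # every group nonempty
            units = tuple(f"u{i}" for i in range(n))
            part = RegionPartition.from_mapping(
                {u: f"g{g}" for u, g in zip(units, labels)},
                tuple(f"g{g}" for g in range(n_groups)),
            )
            d = gini_decompose(x, units, part)
            assert d.overall == pytest.approx(
                d.within + d.between_net + d.transvariation, abs=1e-10
            )
            assert d.within >= 0 and d.between_net >= -1e-15 and d.transvariation >= -1e-15
            for D in d.pair_affluence.values():
                assert -1e-12 <= D <= 1 + 1e-12

    def test_scale_invariance(self, rng, two_region_partition):
        x = rng.uniform(0.1, 1.0, size=4)
        units = ("a1", "a2", "b1", "b2")
        d1 = gini_decompose(x, units, two_region_partition)
        d2 = gini_decompose(x * 37.0, units, two_region_partition)
        assert d2.overall == pytest.approx(d1.overall, rel=1e-12)
        assert d2.within == pytest.approx(d1.within, rel=1e-12)
        assert d2.transvariation == pytest.approx(d1.transvariation, rel=1e-10)

    def test_pairwise_gini_symmetric(self, rng, two_region_partition):
        x = rng.uniform(0.1, 1.0, size=4)
        d = gini_decompose(x, ("a1", "a2", "b1", "b2"), two_region_partition)
        assert d.pair_gini[("A", "B")] == d.pair_gini[("B", "A")]


class TestSeries:
    def test_printed_endpoint_decline(self):
        assert relative_change_pct(0.0978, 0.0583) == pytest.approx(40.39, abs=0.005)

    def test_constant_panel_zero_series(self):
        scores = ScorePanel(("a1", "a2", "b1", "b2"), (2005, 2006),
                            np.full((4, 2), 0.4))
        part = RegionPartition.from_mapping(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        out = gini_series(scores, part)
        np.testing.assert_allclose(out[["G", "G_w", "G_nb", "G_t"]], 0.0, atol=1e-15)

    def test_converging_within_variance_shrinks_gw(self, rng):
        units = tuple(f"u{i}" for i in range(12))
        part = RegionPartition.from_mapping(
            {u: ("A" if i < 6 else "B") for i, u in enumerate(units)}
        )
        base = np.where(np.arange(12) < 6, 0.3, 0.6)
        spread = rng.standard_normal(12)
        years = tuple(range(2005, 2010))
        shrink = np.array([0.08, 0.06, 0.04, 0.02, 0.01])
        scores = base[:, None] + spread[:, None] * shrink[None, :]
        out = gini_series(
            ScorePanel(units, years, np.clip(scores, 0.01, 1)), part
        )
        gw = out["G_w"].to_numpy()
        assert np.all(np.diff(gw) < 1e-12)

    def test_contribution_rates_sum_to_100(self, score_panel, partition):
        out = gini_series(score_panel, partition)
        total = (
            out["contrib_within_pct"]
            + out["contrib_between_pct"]
            + out["contrib_transvar_pct"]
        )
        np.testing.assert_allclose(total, 100.0, atol=1e-6)
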