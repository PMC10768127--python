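"""Class discretization, transition matrices, spatial lag and conditioning."""

import numpy as np
import pytest

from phsupply.entropy_index import ScorePanel
from phsupply.markov_dynamics import (
    ClassSequence,
    SpatialWeights,
    discretize,
    spatial_lag,
    spatial_transition_tensor,
    transition_matrix,
)


def panel_from(matrix, units=None):
    m = np.asarray(matrix, float)
    units = units or tuple(f"u{i}" for i in range(m.shape[0]))
    return ScorePanel(tuple(units), tuple(range(2005, 2005 + m.shape[1])), m)


def classes_from(matrix, k=4):
    m = np.asarray(matrix, int)
    return ClassSequence(
        tuple(f"u{i}" for i in range(m.shape[0])),
        tuple(range(2005, 2005 + m.shape[1])),
        m, np.arange(1, k) / k, k,
    )


class TestDiscretize:
    def test_quartiles_split_evenly(self):
        scores = panel_from(np.array([[0.1, 0.2], [0.3, 0.4], [0.5, 0.6], [0.7, 0.8]]))
        seq = discretize(scores, 4)
        counts = np.bincount(seq.classes.ravel(), minlength=5)[1:]
        np.testing.assert_array_equal(counts, [2, 2, 2, 2])

    def test_explicit_cuts_interval_membership(self):
        scores = panel_from([[0.42]])
        seq = discretize(scores, 4, method="explicit", cuts=(0.3558, 0.3878, 0.4234))
        assert seq.classes[0, 0] == 3

    def test_score_at_cut_point_belongs_below(self):
        scores = panel_from([[0.3558]])
        seq = discretize(scores, 4, method="explicit", cuts=(0.3558, 0.3878, 0.4234))
        assert seq.classes[0, 0] == 1

    def test_constant_units_constant_classes(self):
        scores = panel_from(np.tile([[0.2], [0.4], [0.6], [0.8]], (1, 5)))
        seq = discretize(scores, 4)
        assert np.all(seq.classes == seq.classes[:, [0]])

    def test_too_few_classes_rejected(self, score_panel):
        with pytest.raises(ValueError):
            discretize(score_panel, 1)


class TestTransitionMatrix:
    def test_hand_counted_two_unit_example(self):
        tm = transition_matrix(classes_from([[1, 1, 2], [2, 2, 2]], k=2))
        np.testing.assert_array_equal(tm.counts, [[1, 1], [0, 2]])
        np.testing.assert_allclose(tm.probs[0], [0.5, 0.5])
        np.testing.assert_allclose(tm.probs[1], [0.0, 1.0])

    def test_constant_classes_identity(self):
        tm = transition_matrix(classes_from([[1, 1, 1], [2, 2, 2], [3, 3, 3]], k=3))
        np.testing.assert_allclose(tm.probs, np.eye(3))

    def test_empty_row_reported_nan(self):
        tm = transition_matrix(classes_from([[1, 1]], k=2))
        assert np.isnan(tm.probs[1]).all()

    def test_persistence_chain_diagonal(self):
        """A chain with stay-probability 0.8 yields ~0.8 diagonal estimates."""
        rng = np.random.default_rng(42)
        k, n, T = 4, 60, 40
        states = np.empty((n, T), dtype=int)
        states[:, 0] = rng.integers(1, k + 1, n)
        for t in range(1, T):
            stay = rng.random(n) < 0.8
            move = rng.integers(1, k + 1, n)
            states[:, t] = np.where(stay, states[:, t - 1], move)
        tm = transition_matrix(classes_from(states, k=k))
        diag = np.diag(tm.probs)
        # stay prob is 0.8 + 0.2/k (a random move can land on itself)
        np.testing.assert_allclose(diag, 0.8 + 0.2 / k, atol=0.04)

    def test_row_stochastic(self, score_panel):
        tm = transition_matrix(discretize(score_panel, 4))
        sums = np.nansum(tm.probs, axis=1)
        occupied = tm.row_totals > 0
        np.testing.assert_allclose(sums[occupied], 1.0, atol=1e-12)


class TestSpatialLag:
    def test_two_mutual_neighbors_swap(self):
        w = SpatialWeights.from_adjacency(("u0", "u1"), np.array([[0, 1], [1, 0]]))
        lag = spatial_lag(panel_from([[0.2], [0.6]]), w)
        np.testing.assert_allclose(lag.ravel(), [0.6, 0.2])

    def test_uniform_scores_uniform_lag(self):
        w = SpatialWeights.from_adjacency(
            ("u0", "u1", "u2"), 1 - np.eye(3)
        )
        lag = spatial_lag(panel_from([[0.4], [0.4], [0.4]]), w)
        np.testing.assert_allclose(lag, 0.4)

    def test_matches_matrix_vector_product(self, rng):
        n = 8
        adj = (rng.random((n, n)) < 0.5).astype(float)
        adj = np.maximum(adj, adj.T)
        np.fill_diagonal(adj, 0)
        adj[adj.sum(1) == 0, (np.arange(n) + 1)[adj.sum(1) == 0] % n] = 1
        adj = np.maximum(adj, adj.T)
        units = tuple(f"u{i}" for i in range(n))
        w = SpatialWeights.from_adjacency(units, adj)
        scores = panel_from(rng.uniform(size=(n, 3)), units)
        np.testing.assert_allclose(
            spatial_lag(scores, w), w.matrix @ scores.scores, atol=1e-14
        )

    def test_isolated_unit_named(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1
        with pytest.raises(ValueError, match="u2"):
            SpatialWeights.from_adjacency(("u0", "u1", "u2"), adj)


class TestSpatialTensor:
    def test_degenerate_conditioning_recovers_traditional(self):
        cls = classes_from([[1, 2, 1], [2, 1, 2]], k=2)
        lag = classes_from(np.ones((2, 3), dtype=int), k=2)
        tensor = spatial_transition_tensor(cls, lag)
        tm = transition_matrix(cls)
        np.testing.assert_array_equal(tensor.counts[0], tm.counts)
        assert tensor.counts[1].sum() == 0

    def test_three_unit_line_hand_enumeration(self):
        # classes:      u0: 1,1,2 / u1: 1,2,2 / u2: 2,2,2
        # lag classes:  u0: 1,2,2 / u1: 2,2,2 / u2: 1,2,2
        cls = classes_from([[1, 1, 2], [1, 2, 2], [2, 2, 2]], k=2)
        lag = classes_from([[1, 2, 2], [2, 2, 2], [1, 2, 2]], k=2)
        tensor = spatial_transition_tensor(cls, lag)
        # lag slice 1: (u0,t0): 1->1 ; (u2,t0): 2->2
        np.testing.assert_array_equal(tensor.counts[0], [[1, 0], [0, 1]])
        # lag slice 2: (u0,t1): 1->2 ; (u1,t0): 1->2 ; (u1,t1): 2->2 ; (u2,t1): 2->2
        np.testing.assert_array_equal(tensor.counts[1], [[0, 2], [0, 2]])

    def test_count_conservation(self, score_panel, rng):
        classes = discretize(score_panel, 4)
        lag_vals = rng.uniform(size=score_panel.scores.shape)
        lag_cls = discretize(
            ScorePanel(score_panel.units, score_panel.years, lag_vals),
            4, method="explicit", cuts=classes.cuts,
        )
        tensor = spatial_transition_tensor(classes, lag_cls)
        tm = transition_matrix(classes)
        np.testing.assert_array_equal(tensor.counts.sum(axis=0), tm.counts)

    def test_positive_spillover_raises_upward_mobility(self):
        """Upgrade probability grows with neighbor class on a planted chain."""
        rng = np.random.default_rng(7)
        k, n, T = 3, 300, 30
        cls = np.empty((n, T), dtype=int)
        lag = rng.integers(1, k + 1, (n, T))
        cls[:, 0] = rng.integers(1, k + 1, n)
        for t in range(1, T):
            up_p = 0.1 + 0.2 * (lag[:, t - 1] - 1)      # 0.1/0.3/0.5 by lag class
            up = (rng.random(n) < up_p) & (cls[:, t - 1] < k)
            cls[:, t] = cls[:, t - 1] + up
        tensor = spatial_transition_tensor(classes_from(cls, k), classes_from(lag, k))
        up_prob = []
        for m in range(k):
            c = tensor.counts[m]
            moves_up = sum(c[p, q] for p in range(k) for q in range(k) if q > p)
            at_risk = c[:-1].sum()
            up_prob.append(moves_up / at_risk)
        assert up_prob[0] < up_prob[1] < up_prob[2]
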