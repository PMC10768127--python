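"""Traditional and spatially conditioned Markov transition matrices.

Scores are discretized into K ordered classes (pooled quantile cuts by
default, matching cut points quoted for the whole observation window).
The traditional matrix counts unit transitions between consecutive years,
E_pq = k_pq / k_p.  The spatial variant conditions each transition on the
unit's *spatial lag class* at the origin year — the class of the
neighbor-weighted average score — yielding K conditional K×K matrices whose
counts sum back exactly to the traditional counts.  A diagonal that
strengthens with the lag class is the signature of club convergence with
positive spillover from well-supplied neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy_index import ScorePanel

__all__ = [
    "ClassSequence",
    "TransitionMatrix",
    "SpatialWeights",
    "SpatialTransitionTensor",
    "discretize",
    "transition_matrix",
    "spatial_lag",
    "spatial_transition_tensor",
]


@dataclass(frozen=True)
class ClassSequence:
    units: tuple[str, ...]
    years: tuple[int, ...]
    classes: np.ndarray                 # (n_units, n_years) int, 1..K
    cuts: np.ndarray                    # K-1 interior cut points
    n_classes: int


@dataclass(frozen=True)
class TransitionMatrix:
    counts: np.ndarray                  # (K, K) int
    probs: np.ndarray                   # (K, K), NaN rows where k_p == 0
    row_totals: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        k = self.counts.shape[0]
        rows = [
            {"from": p + 1, "to": q + 1,
             "count": int(self.counts[p, q]), "prob": self.probs[p, q]}
            for p in range(k) for q in range(k)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SpatialWeights:
    units: tuple[str, ...]
    matrix: np.ndarray                  # (n, n), zero diagonal
    row_standardized: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = len(self.units)
        if m.shape != (n, n):
            raise ValueError("weights matrix shape must match unit count")
        if np.any(m < 0):
            raise ValueError("spatial weights must be nonnegative")
        if np.any(np.diag(m) != 0):
            raise ValueError("spatial weights must have a zero diagonal")

    def standardized(self) -> "SpatialWeights":
        """Row-standardize; an isolated unit (all-zero row) raises."""
        if self.row_standardized:
            return self
        sums = self.matrix.sum(axis=1)
        if np.any(sums == 0):
            isolated = [self.units[i] for i in np.where(sums == 0)[0]]
            raise ValueError(f"isolated unit(s) with no neighbors: {isolated}")
        return SpatialWeights(self.units, self.matrix / sums[:, None], True)

    @classmethod
    def from_adjacency(cls, units, adjacency: np.ndarray) -> "SpatialWeights":
        return cls(tuple(units), np.asarray(adjacency, float)).standardized()


@dataclass(frozen=True)
class SpatialTransitionTensor:
    counts: np.ndarray                  # (K, K, K): [lag class, from, to]
    probs: np.ndarray
    n_classes: int

    def slice(self, lag_class: int) -> TransitionMatrix:
        c = self.counts[lag_class - 1]
        return TransitionMatrix(c, self.probs[lag_class - 1], c.sum(axis=1))

    def to_frame(self) -> pd.DataFrame:
        k = self.n_classes
        rows = [
            {"lag_class": m + 1, "from": p + 1, "to": q + 1,
             "count": int(self.counts[m, p, q]), "prob": self.probs[m, p, q]}
            for m in range(k) for p in range(k) for q in range(k)
        ]
        return pd.DataFrame(rows)


def discretize(
    scores: ScorePanel,
    n_classes: int = 4,
    method: str = "pooled-quantile",
    cuts=None,
) -> ClassSequence:
    """Assign each unit-year score to an ordered class 1..K.

    ``pooled-quantile`` takes the K-quantile cut points of all unit-year
    scores over the full window; ``explicit`` uses the supplied interior
    ``cuts``.  Intervals are half-open (lo, hi] with the lowest closed below,
    so a score exactly at a cut point belongs to the lower class.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    s = scores.scores
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if method == "explicit" or cuts is not None:
        c = np.asarray(cuts, dtype=float)
        if len(c) != n_classes - 1 or np.any(np.diff(c) <= 0):
            raise ValueError(f"need {n_classes - 1} strictly increasing cut points")
    elif method == "pooled-quantile":
        qs = np.arange(1, n_classes) / n_classes
        c = np.quantile(s.ravel(), qs)
        if np.any(np.diff(c) <= 0):
            raise ValueError(
                "tied quantile cut points; supply explicit cuts instead"
            )
    else:
        raise ValueError("method must be 'pooled-quantile' or 'explicit'")
    labels = np.searchsorted(c, s, side="left") + 1
    return ClassSequence(scores.units, scores.years, labels, c, n_classes)


def transition_matrix(classes: ClassSequence) -> TransitionMatrix:
    """Count transitions over all unit × consecutive-year pairs."""
    if len(classes.years) < 2:
        raise ValueError("need at least two years")
    k = classes.n_classes
    frm = classes.classes[:, :-1].ravel() - 1
    to = classes.classes[:, 1:].ravel() - 1
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (frm, to), 1)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(totals[:, None] > 0, counts / totals[:, None], np.nan)
    return TransitionMatrix(counts, probs, totals)


def spatial_lag(scores: ScorePanel, weights: SpatialWeights) -> np.ndarray:
    """Neighbor-weighted average score per unit-year: Lag_it = Σ_q W_iq s_qt."""
    w = weights.standardized()
    if w.units != scores.units:
        raise ValueError("weights and scores must cover the same ordered units")
    return w.matrix @ scores.scores


def spatial_transition_tensor(
    classes: ClassSequence, lag_classes: ClassSequence
) -> SpatialTransitionTensor:
    """Transition counts conditioned on the unit's lag class at the origin year."""
    if classes.classes.shape != lag_classes.classes.shape:
        raise ValueError("class and lag-class sequences must share shape")
    k = classes.n_classes
    frm = classes.classes[:, :-1].ravel() - 1
    to = classes.classes[:, 1:].ravel() - 1
    cond = lag_classes.classes[:, :-1].ravel() - 1
    counts = np.zeros((k, k, k), dtype=int)
    np.add.at(counts, (cond, frm, to), 1)
    totals = counts.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(totals[:, :, None] > 0, counts / totals[:, :, None], np.nan)
    return SpatialTransitionTensor(counts, probs, k)
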