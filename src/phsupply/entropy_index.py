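"""Entropy-weight composite index.

The composite public-health-service (PHS) score is a weighted sum of
min-max standardized indicators, with weights derived objectively from the
information entropy of each indicator across all observation rows: the more
an indicator varies, the lower its entropy and the higher its weight.

Steps, with m observation rows (unit-years) and indicators j:

1. standardize: benefit indicators (x - min)/(max - min), cost indicators
   (max - x)/(max - min), min/max over the chosen scope (pooled by default);
2. shares P_ij = x'_ij / sum_i x'_ij, with the 0*ln(0) := 0 convention;
3. entropy e_j = -(1/ln m) * sum_i P_ij ln P_ij, redundancy d_j = 1 - e_j;
4. weights W_j = d_j / sum_j d_j;
5. score PHS_it = sum_j W_j y_itj, bounded in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import IndicatorPanel

__all__ = [
    "StandardizedPanel",
    "WeightVector",
    "ScorePanel",
    "standardize",
    "entropy_weights",
    "compose_score",
    "classify_quintiles",
]


@dataclass(frozen=True)
class StandardizedPanel:
    units: tuple[str, ...]
    years: tuple[int, ...]
    indicators: tuple[str, ...]
    values: np.ndarray                  # (n_units, n_years, n_indicators) in [0,1]
    scope: str = "pooled"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise ValueError("standardized values must lie in [0, 1]")

    def rows(self) -> np.ndarray:
        """(m, n_indicators) observation matrix with m = units × years."""
        return self.values.reshape(-1, len(self.indicators))


@dataclass(frozen=True)
class WeightVector:
    indicators: tuple[str, ...]
    weights: np.ndarray
    entropy: np.ndarray
    redundancy: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if np.any(w < -1e-12):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": self.indicators,
                "entropy": self.entropy,
                "redundancy": self.redundancy,
                "weight": self.weights,
            }
        )


@dataclass(frozen=True)
class ScorePanel:
    """Unit × year composite scores in [0, 1]."""

    units: tuple[str, ...]
    years: tuple[int, ...]
    scores: np.ndarray                  # (n_units, n_years)

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.shape != (len(self.units), len(self.years)):
            raise ValueError("scores shape must be (n_units, n_years)")
        if np.nanmin(s) < -1e-12 or np.nanmax(s) > 1 + 1e-12:
            raise ValueError("scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product([self.units, self.years], names=["unit", "year"])
        return pd.DataFrame({"score": self.scores.ravel()}, index=idx).reset_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScorePanel":
        units = tuple(sorted(df["unit"].astype(str).unique()))
        years = tuple(sorted(int(y) for y in df["year"].unique()))
        cube = (
            df.set_index(["unit", "year"])["score"]
            .reindex(pd.MultiIndex.from_product([units, years]))
            .to_numpy()
            .reshape(len(units), len(years))
        )
        return cls(units, years, cube)

    def year_values(self, year: int) -> np.ndarray:
        return self.scores[:, self.years.index(year)]


def standardize(panel: IndicatorPanel, scope: str = "pooled") -> StandardizedPanel:
    """Min-max standardize each indicator respecting its direction flag.

    ``scope="pooled"`` takes one min/max per indicator over all unit-years
    (scores stay comparable across years); ``scope="per-year"`` rescales
    within each year separately.  A constant indicator (max == min) maps to
    all zeros with a warning — it carries no information and will receive
    entropy weight zero downstream.
    """
    if panel.missing_mask.any():
        raise ValueError("panel contains missing values; interpolate first")
    if scope not in ("pooled", "per-year"):
        raise ValueError("scope must be 'pooled' or 'per-year'")
    v = panel.values
    direction = np.asarray(panel.direction)
    axis = (0, 1) if scope == "pooled" else 0
    lo = v.min(axis=axis, keepdims=True)
    hi = v.max(axis=axis, keepdims=True)
    rng = hi - lo
    constant = rng == 0
    if constant.any():
        flat = np.unique(np.where(np.broadcast_to(constant, v.shape))[-1])
        names = [panel.indicators[j] for j in flat]
        warnings.warn(
            f"constant indicator(s) {names} standardized to 0 (zero range)",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, rng)
    std = np.where(direction > 0, (v - lo) / safe, (hi - v) / safe)
    std = np.where(np.broadcast_to(constant, v.shape), 0.0, std)
    return StandardizedPanel(panel.units, panel.years, panel.indicators, std, scope)


def entropy_weights(std: StandardizedPanel, epsilon_shift: float = 0.0) -> WeightVector:
    """Objective weights from the Shannon entropy of each indicator column.

    ``epsilon_shift`` optionally adds a small positive offset to the
    standardized values before forming shares (the alternative to the
    0*ln(0) := 0 limit convention; default keeps the limit convention).
    """
    x = std.rows()
    m = x.shape[0]
    if m < 2:
        raise ValueError("need at least 2 observation rows")
    if epsilon_shift:
        x = x + epsilon_shift
    col_sum = x.sum(axis=0)
    e = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        if col_sum[j] == 0:
            # all-zero column: no information, maximal entropy by convention
            e[j] = 1.0
            continue
        p = x[:, j] / col_sum[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        e[j] = -plogp.sum() / np.log(m)
    d = 1.0 - e
    d = np.where(np.abs(d) < 1e-15, 0.0, d)
    if d.sum() == 0:
        raise ValueError("every indicator is constant; weights undefined")
    w = d / d.sum()
    return WeightVector(std.indicators, w, e, d)


def compose_score(std: StandardizedPanel, weights: WeightVector) -> ScorePanel:
    """PHS_it = Σ_j W_j · y_itj over the standardized values."""
    if weights.indicators != std.indicators:
        raise ValueError("weight indicator set does not match the panel")
    scores = np.einsum("utj,j->ut", std.values, weights.weights)
    return ScorePanel(std.units, std.years, np.clip(scores, 0.0, 1.0))


QUINTILE_LABELS = ("low", "lower-middle", "medium", "upper-middle", "high")


def classify_quintiles(
    scores: ScorePanel,
    breaks=None,
    labels: tuple[str, ...] = QUINTILE_LABELS,
) -> pd.DataFrame:
    """Assign each unit-year score to one of five ordered level bands.

    With explicit ``breaks`` (four interior cut points, strictly increasing)
    the bands are (-inf, b1], (b1, b2], ..., (b4, +inf); without, equal-width
    bands over the observed score range are used.  Returns a long frame with
    columns unit, year, score, level.
    """
    s = scores.scores
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if breaks is not None:
        cuts = np.asarray(breaks, dtype=float)
        if cuts.ndim != 1 or len(cuts) != len(labels) - 1:
            raise ValueError(f"need {len(labels) - 1} interior break points")
        if np.any(np.diff(cuts) <= 0):
            raise ValueError("breaks must be strictly increasing")
    else:
        lo, hi = s.min(), s.max()
        if hi == lo:
            level = np.zeros_like(s, dtype=int)
            out = scores.to_frame()
            out["level"] = labels[0]
            return out
        cuts = lo + (hi - lo) * np.arange(1, len(labels)) / len(labels)
    # right-closed intervals: score <= b1 -> band 1, etc.
    level = np.searchsorted(cuts, s, side="left")
    out = scores.to_frame()
    out["level"] = np.asarray(labels)[level.ravel()]
    return out
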