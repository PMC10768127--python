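"""Weighted standard deviation ellipse (SDE) of a spatial point pattern.

The SDE summarizes where a weighted point set sits (mean center), how spread
it is along two orthogonal axes (σ_x, σ_y), and which way it points (azimuth
θ, degrees clockwise from north of the major axis).  Weighting the city
centroids by their composite score gives the center of gravity and dominant
direction of service supply, and tracking those across years gives the
drift of the pattern.

Geographic (lon/lat) input is projected to planar km by an equirectangular
projection about the mean latitude before the second moments are taken.

The azimuth solves

    tan θ = [ (Σw x̃² − Σw ỹ²) + sqrt((Σw x̃² − Σw ỹ²)² + 4 (Σw x̃ ỹ)²) ]
            / (2 Σw x̃ ỹ)

with deviations x̃, ỹ about the weighted mean center; then

    σ_x = sqrt( Σ w (x̃ cos θ − ỹ sin θ)² / Σw )   (axis rotated θ from east)
    σ_y = sqrt( Σ w (x̃ sin θ + ỹ cos θ)² / Σw )   (axis rotated θ from north)

The ``printed`` normalization variant divides by Σw² and weights the
deviations twice (w inside the square), matching a formula sometimes seen in
the applied literature; the conventional form above is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import CentroidTable

__all__ = ["EllipseSummary", "weighted_mean_center", "sde", "track_center"]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class EllipseSummary:
    center_x: float
    center_y: float
    sigma_x: float                      # std. deviation along the rotated-east axis
    sigma_y: float                      # std. deviation along the rotated-north axis
    azimuth_deg: float                  # major-axis azimuth, clockwise from north, [0, 180)
    area: float                         # π σ_x σ_y
    year: int | None = None
    degenerate: bool = False            # collinear input (minor σ == 0)

    @property
    def major(self) -> float:
        return max(self.sigma_x, self.sigma_y)

    @property
    def minor(self) -> float:
        return min(self.sigma_x, self.sigma_y)


def _planar(centroids: CentroidTable) -> tuple[np.ndarray, np.ndarray]:
    x, y = centroids.x, centroids.y
    if centroids.geographic:
        lat0 = math.radians(float(np.mean(y)))
        x = np.radians(x) * EARTH_RADIUS_KM * math.cos(lat0)
        y = np.radians(y) * EARTH_RADIUS_KM
    return np.asarray(x, float), np.asarray(y, float)


def weighted_mean_center(
    centroids: CentroidTable, weights: np.ndarray
) -> tuple[float, float]:
    """Weighted arithmetic mean of the (projected) coordinates."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(centroids.units),):
        raise ValueError("one weight per unit required")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    x, y = _planar(centroids)
    return float(x @ w / total), float(y @ w / total)


def sde(
    centroids: CentroidTable,
    weights: np.ndarray,
    *,
    year: int | None = None,
    normalization: str = "conventional",
) -> EllipseSummary:
    """Weighted standard deviation ellipse of the point pattern."""
    if normalization not in ("conventional", "printed"):
        raise ValueError("normalization must be 'conventional' or 'printed'")
    w = np.asarray(weights, dtype=float)
    cx, cy = weighted_mean_center(centroids, w)
    x, y = _planar(centroids)
    dx, dy = x - cx, y - cy

    if normalization == "conventional":
        a = w @ (dx * dx) - w @ (dy * dy)
        b = w @ (dx * dy)
        denom = w.sum()
        wx, wy = np.sqrt(w) * dx, np.sqrt(w) * dy
    else:
        w2 = w * w
        a = w2 @ (dx * dx) - w2 @ (dy * dy)
        b = w2 @ (dx * dy)
        denom = w2.sum()
        wx, wy = w * dx, w * dy

    if b == 0.0:
        theta = 0.0 if a <= 0 else math.pi / 2
    else:
        theta = math.atan((a + math.hypot(a, 2 * b)) / (2 * b))
        if theta < 0:
            theta += math.pi

    c, s = math.cos(theta), math.sin(theta)
    sigma_x = math.sqrt(np.sum((wx * c - wy * s) ** 2) / denom)
    sigma_y = math.sqrt(np.sum((wx * s + wy * c) ** 2) / denom)

    # report the azimuth of the *major* axis clockwise from north
    if sigma_y >= sigma_x:
        az = math.degrees(theta)
    else:
        az = math.degrees(theta) + 90.0
    az %= 180.0
    degenerate = min(sigma_x, sigma_y) < 1e-12 * max(sigma_x, sigma_y, 1.0)
    return EllipseSummary(
        cx, cy, sigma_x, sigma_y, az, math.pi * sigma_x * sigma_y, year, degenerate
    )


def track_center(summaries: list[EllipseSummary]) -> pd.DataFrame:
    """Per-interval displacement (distance, compass bearing) of the mean center.

    Bearing is degrees clockwise from north in [0, 360); NaN when the center
    does not move.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two yearly summaries")
    rows = []
    for a, b in zip(summaries[:-1], summaries[1:]):
        dx, dy = b.center_x - a.center_x, b.center_y - a.center_y
        dist = math.hypot(dx, dy)
        bearing = math.degrees(math.atan2(dx, dy)) % 360.0 if dist > 0 else math.nan
        rows.append(
            {
                "from_year": a.year,
                "to_year": b.year,
                "distance": dist,
                "bearing_deg": bearing,
            }
        )
    return pd.DataFrame(rows)
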