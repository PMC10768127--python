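"""Spatial pattern of supply: weighted standard deviation ellipses by year.

Weights each city's centroid by its composite score, summarises the pattern
per year (center, axes, azimuth, area) and tracks the drift of the center of
gravity.  Writes results/sde.csv and results/sde_track.csv.
"""

from pathlib import Path

import pandas as pd

from phsupply import entropy_index, panel_io, sde_geometry

ROOT = Path(__file__).resolve().parent.parent / "results"

scores = entropy_index.ScorePanel.from_frame(pd.read_csv(ROOT / "scores.csv"))
centroids = panel_io.read_centroids(ROOT / "inputs" / "centroids.csv").reorder(scores.units)

summaries = [
    sde_geometry.sde(centroids, scores.year_values(y), year=y) for y in scores.years
]
pd.DataFrame(
    [{"year": s.year, "center_x": s.center_x, "center_y": s.center_y,
      "sigma_x": s.sigma_x, "sigma_y": s.sigma_y,
      "azimuth_deg": s.azimuth_deg, "area": s.area} for s in summaries]
).to_csv(ROOT / "sde.csv", index=False)
track = sde_geometry.track_center(summaries)
track.to_csv(ROOT / "sde_track.csv", index=False)

first, last = summaries[0], summaries[-1]
print(f"azimuth {first.azimuth_deg:.2f} deg ({first.year}) -> "
      f"{last.azimuth_deg:.2f} deg ({last.year}); "
      f"ellipse area {first.area:.1f} -> {last.area:.1f}")
total = track["distance"].sum()
print(f"center of gravity moved {total:.2f} distance units over "
      f"{len(track)} intervals")
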