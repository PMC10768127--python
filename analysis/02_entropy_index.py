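"""Score the province: entropy weights and the composite supply index.

Standardizes the 20 directional indicators over the pooled 17-year window,
derives objective entropy weights, and composes the per-city-year score.
Writes results/scores.csv and results/weights.csv and prints the weight
spread and score trajectory.
"""

from pathlib import Path

import pandas as pd

from phsupply import entropy_index, panel_io

ROOT = Path(__file__).resolve().parent.parent / "results"

schema = panel_io.read_schema(ROOT / "inputs" / "schema.yaml")
panel = panel_io.interpolate_missing(panel_io.read_panel(ROOT / "inputs" / "panel.csv", schema))
std = entropy_index.standardize(panel, scope="pooled")
weights = entropy_index.entropy_weights(std)
scores = entropy_index.compose_score(std, weights)

weights.to_frame().to_csv(ROOT / "weights.csv", index=False)
scores.to_frame().to_csv(ROOT / "scores.csv", index=False)

w = weights.to_frame()
yearly = scores.to_frame().groupby("year")["score"].mean()
print(f"entropy weights: sum={w['weight'].sum():.6f}, "
      f"range [{w['weight'].min():.4f}, {w['weight'].max():.4f}]")
print(f"provincial mean score rose {yearly.iloc[0]:.4f} -> {yearly.iloc[-1]:.4f} "
      f"over {yearly.index[0]}-{yearly.index[-1]}")
levels = entropy_index.classify_quintiles(scores)
print("quintile occupancy:", levels["level"].value_counts().to_dict())
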