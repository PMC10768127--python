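"""Class mobility: traditional and spatially conditioned Markov chains.

Discretizes scores into pooled quartile classes, estimates the transition
matrix and the K conditional matrices given the neighbors' class, and prints
the persistence diagonal — the club-convergence signature.  Writes
results/transition_matrix.csv and results/spatial_transition_tensor.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phsupply import entropy_index, markov_dynamics
from phsupply.pipeline import _read_adjacency

ROOT = Path(__file__).resolve().parent.parent / "results"

scores = entropy_index.ScorePanel.from_frame(pd.read_csv(ROOT / "scores.csv"))
classes = markov_dynamics.discretize(scores, 4)
tm = markov_dynamics.transition_matrix(classes)
tm.to_frame().to_csv(ROOT / "transition_matrix.csv", index=False)

weights = _read_adjacency(ROOT / "inputs" / "adjacency.csv", scores.units)
lag = markov_dynamics.spatial_lag(scores, weights)
lag_classes = markov_dynamics.discretize(
    entropy_index.ScorePanel(scores.units, scores.years, np.clip(lag, 0, 1)),
    4, method="explicit", cuts=classes.cuts,
)
tensor = markov_dynamics.spatial_transition_tensor(classes, lag_classes)
tensor.to_frame().to_csv(ROOT / "spatial_transition_tensor.csv", index=False)

diag = np.diag(tm.probs)
print("quartile cuts:", np.round(classes.cuts, 4).tolist())
print("persistence diagonal:", [f"{d:.2%}" for d in diag])
up = np.triu(tm.counts, 1).sum()
down = np.tril(tm.counts, -1).sum()
print(f"upward moves {up} vs downward {down} "
      f"(counts conserved across tensor slices: "
      f"{np.array_equal(tensor.counts.sum(axis=0), tm.counts)})")
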