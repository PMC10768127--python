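"""Dagum Gini coefficient and its three-way decomposition.

For one cross-section of unit scores split into regions, the overall Gini

    G = Σ_i Σ_r |x_i − x_r| / (2 n² ȳ)

decomposes additively (Dagum 1997) into

* G_w  — within-group component: Σ_j G_jj p_j s_j with the group Gini
  G_jj = Σ|x_ji − x_jr| / (2 n_j² ȳ_j), population share p_j = n_j/n and
  value share s_j = n_j ȳ_j / (n ȳ);
* G_nb — net between-group component: Σ_{j>h} G_jh (p_j s_h + p_h s_j) D_jh;
* G_t  — transvariation (the paper's "supervariable density"): the same sum
  weighted by (1 − D_jh), the part of between-group inequality generated by
  overlapping group distributions.

Here G_jh = Σ_i Σ_r |x_ji − x_hr| / (n_j n_h (ȳ_j + ȳ_h)) is the pairwise
between-group Gini, and the relative economic affluence

    D_jh = (d_jh − p_jh) / (d_jh + p_jh)

uses the gross affluence d_jh = E[(x_j − x_h)⁺] and first-order
transvariation moment p_jh = E[(x_h − x_j)⁺] taken over all cross-group
pairs, with group j the higher-mean one of the pair so D_jh ∈ [0, 1].
G = G_w + G_nb + G_t holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy_index import ScorePanel
from .panel_io import RegionPartition

__all__ = ["GiniDecomposition", "gini_overall", "gini_decompose", "gini_series",
           "relative_change_pct"]


@dataclass(frozen=True)
class GiniDecomposition:
    overall: float
    within: float
    between_net: float
    transvariation: float
    group_gini: dict[str, float]            # G_jj per region
    pair_gini: dict[tuple[str, str], float]  # G_jh, keyed (region_a, region_b)
    pair_affluence: dict[tuple[str, str], float]  # D_jh on the same keys
    pop_share: dict[str, float]             # p_j
    value_share: dict[str, float]           # s_j
    year: int | None = None

    def _rate(self, part: float) -> float:
        if self.overall == 0.0:
            return 0.0                      # perfectly equal cross-section
        return 100.0 * part / self.overall

    @property
    def contribution_within(self) -> float:
        return self._rate(self.within)

    @property
    def contribution_between(self) -> float:
        return self._rate(self.between_net)

    @property
    def contribution_transvariation(self) -> float:
        return self._rate(self.transvariation)


def gini_overall(values: np.ndarray) -> float:
    """Gini over all ordered pairs: Σ|x_i − x_r| / (2 n² ȳ), ȳ the grand mean."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-d sample with n >= 2")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("Gini is undefined for a nonpositive mean")
    diff = np.abs(x[:, None] - x[None, :]).sum()
    return float(diff / (2.0 * len(x) ** 2 * mean))


def gini_decompose(
    values: np.ndarray,
    units,
    partition: RegionPartition,
    *,
    year: int | None = None,
) -> GiniDecomposition:
    """Full Dagum decomposition of one cross-section."""
    x = np.asarray(values, dtype=float)
    labels = partition.labels_for(units)
    regions = [r for r in partition.regions if (labels == r).any()]
    n, grand = len(x), x.mean()
    if grand <= 0:
        raise ValueError("Gini is undefined for a nonpositive mean")
    groups = {r: x[labels == r] for r in regions}
    means = {r: g.mean() for r, g in groups.items()}
    for r, m in means.items():
        if m <= 0:
            raise ValueError(f"region {r!r} has a nonpositive mean")
    p = {r: len(g) / n for r, g in groups.items()}
    s = {r: len(g) * means[r] / (n * grand) for r, g in groups.items()}

    g_jj = {
        r: float(np.abs(g[:, None] - g[None, :]).sum() / (2 * len(g) ** 2 * means[r]))
        for r, g in groups.items()
    }
    g_w = sum(g_jj[r] * p[r] * s[r] for r in regions)

    g_jh: dict[tuple[str, str], float] = {}
    d_jh: dict[tuple[str, str], float] = {}
    g_nb = g_t = 0.0
    for a_idx in range(len(regions)):
        for b_idx in range(a_idx):
            ra, rb = regions[a_idx], regions[b_idx]
            ga, gb = groups[ra], groups[rb]
            diff = ga[:, None] - gb[None, :]
            pair_g = float(
                np.abs(diff).sum() / (len(ga) * len(gb) * (means[ra] + means[rb]))
            )
            # orient so "j" is the higher-mean group (region order breaks ties)
            if means[ra] >= means[rb]:
                gross = float(np.clip(diff, 0, None).mean())       # d_jh
                trans = float(np.clip(-diff, 0, None).mean())      # p_jh
            else:
                gross = float(np.clip(-diff, 0, None).mean())
                trans = float(np.clip(diff, 0, None).mean())
            d = (gross - trans) / (gross + trans) if gross + trans > 0 else 0.0
            g_jh[(ra, rb)] = g_jh[(rb, ra)] = pair_g
            d_jh[(ra, rb)] = d_jh[(rb, ra)] = d
            w_pair = pair_g * (p[ra] * s[rb] + p[rb] * s[ra])
            g_nb += w_pair * d
            g_t += w_pair * (1.0 - d)

    overall = gini_overall(x)
    return GiniDecomposition(
        overall, float(g_w), float(g_nb), float(g_t),
        g_jj, g_jh, d_jh, p, s, year,
    )


def gini_series(scores: ScorePanel, partition: RegionPartition) -> pd.DataFrame:
    """Yearly Dagum decompositions as a tidy table.

    Columns: year, G, G_w, G_nb, G_t, the three contribution rates (percent),
    one ``G_<region>`` column per region, and one ``G_<a>__<b>`` column per
    region pair.
    """
    rows = []
    for t, year in enumerate(scores.years):
        d = gini_decompose(scores.scores[:, t], scores.units, partition, year=year)
        row = {
            "year": year,
            "G": d.overall,
            "G_w": d.within,
            "G_nb": d.between_net,
            "G_t": d.transvariation,
            "contrib_within_pct": d.contribution_within,
            "contrib_between_pct": d.contribution_between,
            "contrib_transvar_pct": d.contribution_transvariation,
        }
        for r, g in d.group_gini.items():
            row[f"G_{r}"] = g
        seen = set()
        for (a, b), g in d.pair_gini.items():
            key = tuple(sorted((a, b)))
            if key not in seen:
                seen.add(key)
                row[f"G_{key[0]}__{key[1]}"] = g
        rows.append(row)
    return pd.DataFrame(rows)


def relative_change_pct(first: float, last: float) -> float:
    """Percentage change 100·(G_a − G_b)/G_a between two coefficients."""
    if first == 0:
        raise ValueError("relative change undefined from a zero baseline")
    return 100.0 * (first - last) / first
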