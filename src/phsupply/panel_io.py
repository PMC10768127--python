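"""Data model and I/O for the city × year × indicator panel.

The analysis consumes four tables:

* an :class:`IndicatorPanel` of raw directional indicators (benefit ``+1`` /
  cost ``-1``) for every prefecture-level unit and year,
* a :class:`RegionPartition` mapping units to macro-regions,
* a :class:`CentroidTable` of unit coordinates (planar or lon/lat) with
  optional weights,
* a :class:`CovariatePanel` holding the composite score and the regression
  covariates (lnPGDP, FSS, lnDEN, UR, ISU).

Long CSV (``unit,year,indicator,value``) is the canonical interchange format;
wide CSV (one column per indicator) is accepted and converted.  Units are
ordered lexicographically everywhere so that transition counts and Gini sums
are reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IndicatorPanel",
    "RegionPartition",
    "CentroidTable",
    "CovariatePanel",
    "read_schema",
    "read_panel",
    "write_panel",
    "read_partition",
    "read_centroids",
    "read_covariates",
    "interpolate_missing",
    "align",
]

COVARIATE_COLUMNS = ("PHS", "lnPGDP", "FSS", "lnDEN", "UR", "ISU")
LOG_COLUMNS = ("lnPGDP", "lnDEN")


@dataclass(frozen=True)
class IndicatorPanel:
    """Unit × year × indicator value cube with per-indicator direction flags."""

    units: tuple[str, ...]
    years: tuple[int, ...]
    indicators: tuple[str, ...]
    direction: tuple[int, ...]          # +1 benefit, -1 cost, aligned with indicators
    values: np.ndarray                  # (n_units, n_years, n_indicators), NaN = missing

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.units), len(self.years), len(self.indicators)):
            raise ValueError(
                f"values shape {values.shape} does not match axes "
                f"({len(self.units)}, {len(self.years)}, {len(self.indicators)})"
            )
        if len(self.direction) != len(self.indicators):
            raise ValueError("one direction flag per indicator required")
        if any(d not in (-1, 1) for d in self.direction):
            raise ValueError("direction flags must be +1 or -1")
        yrs = np.asarray(self.years)
        if len(yrs) > 1 and not np.all(np.diff(yrs) > 0):
            raise ValueError("years must be strictly increasing")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    def to_long(self) -> pd.DataFrame:
        """Long-format DataFrame (unit, year, indicator, value); NaN rows kept."""
        idx = pd.MultiIndex.from_product(
            [self.units, self.years, self.indicators],
            names=["unit", "year", "indicator"],
        )
        return pd.DataFrame({"value": self.values.ravel()}, index=idx).reset_index()


@dataclass(frozen=True)
class RegionPartition:
    """Unit → region mapping with a fixed region order."""

    mapping: dict[str, str]
    regions: tuple[str, ...]

    def __post_init__(self):
        missing = set(self.mapping.values()) - set(self.regions)
        if missing:
            raise ValueError(f"regions {sorted(missing)} used but not declared")
        if len(self.regions) < 2:
            raise ValueError("need >=2 regions for a between-group decomposition")

    @classmethod
    def from_mapping(cls, mapping: dict[str, str], regions=None) -> "RegionPartition":
        if regions is None:
            seen: list[str] = []
            for r in mapping.values():
                if r not in seen:
                    seen.append(r)
            regions = tuple(seen)
        return cls(dict(mapping), tuple(regions))

    def members(self, region: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, r in self.mapping.items() if r == region))

    def labels_for(self, units) -> np.ndarray:
        try:
            return np.array([self.mapping[u] for u in units])
        except KeyError as e:
            raise KeyError(f"unit {e.args[0]!r} not present in the region partition") from e


@dataclass(frozen=True)
class CentroidTable:
    """Per-unit planar or geographic coordinates with optional positive weights."""

    units: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray
    weight: np.ndarray | None = None
    geographic: bool = False            # True when x/y are lon/lat degrees

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("coordinates must be finite")
        if len(x) != len(self.units) or len(y) != len(self.units):
            raise ValueError("one coordinate pair per unit required")
        if self.weight is not None:
            w = np.asarray(self.weight, dtype=float)
            object.__setattr__(self, "weight", w)
            if np.any(w <= 0):
                raise ValueError("weights must be positive")

    def reorder(self, units) -> "CentroidTable":
        pos = {u: i for i, u in enumerate(self.units)}
        idx = np.array([pos[u] for u in units])
        w = None if self.weight is None else self.weight[idx]
        return CentroidTable(tuple(units), self.x[idx], self.y[idx], w, self.geographic)


@dataclass(frozen=True)
class CovariatePanel:
    """Balanced unit × year covariate table (PHS, lnPGDP, FSS, lnDEN, UR, ISU)."""

    frame: pd.DataFrame                 # columns: unit, year, then covariates
    log_columns: tuple[str, ...] = LOG_COLUMNS

    def __post_init__(self):
        f = self.frame
        for col in ("unit", "year"):
            if col not in f.columns:
                raise ValueError(f"covariate frame must contain a {col!r} column")
        counts = f.groupby("unit")["year"].nunique()
        n_years = f["year"].nunique()
        if not (counts == n_years).all():
            bad = counts[counts != n_years].index.tolist()
            raise ValueError(f"panel is unbalanced for units {bad}")
        if f.duplicated(["unit", "year"]).any():
            raise ValueError("duplicate (unit, year) rows in covariate panel")
        f = f.sort_values(["unit", "year"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "frame", f)

    @property
    def units(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["unit"].unique()))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.frame["year"].unique()))

    @property
    def n_obs(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers / writers


def read_schema(path) -> dict:
    """Read the YAML schema declaring indicator directions (and optional tiers).

    Expected layout::

        indicators:
          beds_per_1000: {direction: +1, tier: input}
          avg_hospital_stay: {direction: -1, tier: output}
    """
    with open(path, "r", encoding="utf-8") as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, dict) or "indicators" not in schema:
        raise ValueError("schema must be a mapping with an 'indicators' key")
    for name, meta in schema["indicators"].items():
        if not isinstance(meta, dict) or "direction" not in meta:
            raise ValueError(f"indicator {name!r} lacks a direction flag")
        if int(meta["direction"]) not in (-1, 1):
            raise ValueError(f"indicator {name!r}: direction must be +1 or -1")
    return schema


def _panel_from_long(df: pd.DataFrame, directions: dict[str, int]) -> IndicatorPanel:
    dup = df.duplicated(["unit", "year", "indicator"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            "duplicate (unit, year, indicator) triple: "
            f"({row['unit']!r}, {row['year']!r}, {row['indicator']!r})"
        )
    unknown = set(df["indicator"].unique()) - set(directions)
    if unknown:
        raise ValueError(f"indicators {sorted(unknown)} not declared in schema")
    units = tuple(sorted(df["unit"].astype(str).unique()))
    years = tuple(sorted(int(y) for y in df["year"].unique()))
    indicators = tuple(directions)      # schema order
    cube = (
        df.set_index(["unit", "year", "indicator"])["value"]
        .reindex(pd.MultiIndex.from_product([units, years, indicators]))
        .to_numpy()
        .reshape(len(units), len(years), len(indicators))
    )
    return IndicatorPanel(
        units, years, indicators, tuple(int(directions[j]) for j in indicators), cube
    )


def read_panel(path, schema: dict, *, sep: str = ",") -> IndicatorPanel:
    """Read a long or wide indicator CSV/TSV into an :class:`IndicatorPanel`.

    Long format has columns ``unit, year, indicator, value``; wide format has
    ``unit, year`` plus one column per indicator.  The format is detected from
    the header.
    """
    directions = {k: int(v["direction"]) for k, v in schema["indicators"].items()}
    df = pd.read_csv(path, sep=sep)
    cols = set(df.columns)
    if {"unit", "year", "indicator", "value"} <= cols:
        return _panel_from_long(df, directions)
    if {"unit", "year"} <= cols:
        value_cols = [c for c in df.columns if c not in ("unit", "year")]
        unknown = set(value_cols) - set(directions)
        if unknown:
            raise ValueError(f"indicators {sorted(unknown)} not declared in schema")
        long = df.melt(
            id_vars=["unit", "year"], value_vars=value_cols,
            var_name="indicator", value_name="value",
        )
        return _panel_from_long(long, directions)
    raise ValueError("unrecognized panel layout: need long or wide columns")


def write_panel(panel: IndicatorPanel, path) -> None:
    """Write a panel as long CSV (lossless round-trip with :func:`read_panel`)."""
    panel.to_long().to_csv(path, index=False)


def read_partition(path, *, sep: str = ",") -> RegionPartition:
    df = pd.read_csv(path, sep=sep)
    if not {"unit", "region"} <= set(df.columns):
        raise ValueError("partition table needs 'unit' and 'region' columns")
    if df["unit"].duplicated().any():
        raise ValueError("a unit is mapped to more than one region")
    return RegionPartition.from_mapping(
        dict(zip(df["unit"].astype(str), df["region"].astype(str)))
    )


def read_centroids(path, *, sep: str = ",", geographic: bool = False) -> CentroidTable:
    df = pd.read_csv(path, sep=sep).sort_values("unit", kind="mergesort")
    if not {"unit", "x", "y"} <= set(df.columns):
        raise ValueError("centroid table needs 'unit', 'x' and 'y' columns")
    w = df["weight"].to_numpy(float) if "weight" in df.columns else None
    return CentroidTable(
        tuple(df["unit"].astype(str)), df["x"].to_numpy(float),
        df["y"].to_numpy(float), w, geographic,
    )


def read_covariates(path, *, sep: str = ",") -> CovariatePanel:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")
    return CovariatePanel(df)


# ---------------------------------------------------------------------------
# missing data


def interpolate_missing(panel: IndicatorPanel) -> IndicatorPanel:
    """Fill missing cells by linear interpolation along the year axis.

    Interior gaps are interpolated linearly between the bracketing observed
    years; leading and trailing gaps take the nearest observed value.  A
    unit-indicator series with fewer than two observations cannot anchor a
    line and raises.
    """
    values = panel.values.copy()
    years = np.asarray(panel.years, dtype=float)
    for i, unit in enumerate(panel.units):
        for j, ind in enumerate(panel.indicators):
            series = values[i, :, j]
            obs = ~np.isnan(series)
            if obs.all():
                continue
            if obs.sum() < 2:
                raise ValueError(
                    f"series for unit {unit!r}, indicator {ind!r} has "
                    f"{int(obs.sum())} observed value(s); need >=2 to interpolate"
                )
            series[~obs] = np.interp(years[~obs], years[obs], series[obs])
    return replace(panel, values=values)


# ---------------------------------------------------------------------------
# joining


def align(
    panel: IndicatorPanel,
    covariates: CovariatePanel,
    partition: RegionPartition,
) -> pd.DataFrame:
    """Join covariates and region labels into one frame keyed by (unit, year).

    All three inputs must cover identical unit sets (and the covariates the
    same years as the panel); the output is ordered by unit then year.
    """
    p_units, c_units = set(panel.units), set(covariates.units)
    r_units = set(partition.mapping)
    for name, other in (("covariates", c_units), ("partition", r_units)):
        if other != p_units:
            diff = sorted(p_units.symmetric_difference(other))
            raise ValueError(f"unit sets differ between panel and {name}: {diff}")
    if set(covariates.years) != set(panel.years):
        diff = sorted(set(covariates.years).symmetric_difference(panel.years))
        raise ValueError(f"year sets differ between panel and covariates: {diff}")
    out = covariates.frame.copy()
    out["region"] = partition.labels_for(out["unit"])
    return out.sort_values(["unit", "year"], kind="mergesort").reset_index(drop=True)
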