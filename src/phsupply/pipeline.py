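"""End-to-end orchestration: index → ellipse → densities → Markov → Gini →
regression → thresholds, from one validated config.

Each stage is a pure function over files: the resolved config (all defaults
materialized) is written next to the outputs, and a JSON manifest with
SHA-256 checksums makes reruns verifiable.  With ``allow_partial`` a missing
adjacency input only skips the spatial-Markov stage instead of aborting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    dagum_gini,
    density_dynamics,
    entropy_index,
    markov_dynamics,
    panel_econometrics,
    panel_io,
    sde_geometry,
    threshold_effects,
)

log = logging.getLogger("phsupply")

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    panel_csv: str
    schema_yaml: str
    partition_csv: str
    centroids_csv: str
    covariates_csv: str
    output_dir: str
    adjacency_csv: str | None = None
    normalization_scope: str = "pooled"
    n_classes: int = 4
    class_cuts: list | None = None
    kde_bandwidth: str | float = "auto"
    kde_kernel: str = "gaussian"
    estimator_robust: str = "cluster"
    threshold_regime_vars: list = field(default_factory=lambda: ["UR", "FSS"])
    threshold_n: int = 2
    threshold_B: int = 300
    threshold_trim: float = 0.01
    seed: int = 0
    allow_partial: bool = False
    geographic_coords: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for name in ("panel_csv", "schema_yaml", "partition_csv",
                     "centroids_csv", "covariates_csv"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.adjacency_csv is not None and not Path(self.adjacency_csv).exists():
            if not self.allow_partial:
                raise FileNotFoundError(f"adjacency_csv: {self.adjacency_csv}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_adjacency(path, units) -> markov_dynamics.SpatialWeights:
    df = pd.read_csv(path)
    pos = {u: i for i, u in enumerate(units)}
    m = np.zeros((len(units), len(units)))
    for _, row in df.iterrows():
        m[pos[str(row["unit_a"])], pos[str(row["unit_b"])]] = row.get("weight", 1.0)
    m = np.maximum(m, m.T)              # symmetrize
    return markov_dynamics.SpatialWeights.from_adjacency(units, m)


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        artifacts.append(p)
        log.info("wrote %s", p)

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("index")
        schema = panel_io.read_schema(config.schema_yaml)
        panel = panel_io.interpolate_missing(
            panel_io.read_panel(config.panel_csv, schema)
        )
        std = entropy_index.standardize(panel, scope=config.normalization_scope)
        weights = entropy_index.entropy_weights(std)
        scores = entropy_index.compose_score(std, weights)
        save(weights.to_frame(), "weights.csv")
        save(scores.to_frame(), "scores.csv")

        partition = panel_io.read_partition(config.partition_csv)
        centroids = panel_io.read_centroids(
            config.centroids_csv, geographic=config.geographic_coords
        ).reorder(scores.units)

        stage("sde")
        summaries = [
            sde_geometry.sde(centroids, scores.year_values(y), year=y)
            for y in scores.years
        ]
        save(
            pd.DataFrame(
                [
                    {"year": s.year, "center_x": s.center_x, "center_y": s.center_y,
                     "sigma_x": s.sigma_x, "sigma_y": s.sigma_y,
                     "azimuth_deg": s.azimuth_deg, "area": s.area}
                    for s in summaries
                ]
            ),
            "sde.csv",
        )
        save(sde_geometry.track_center(summaries), "sde_track.csv")

        stage("kde")
        save(
            density_dynamics.dynamics_table(
                scores, partition.mapping,
                h=config.kde_bandwidth, kernel=config.kde_kernel,
            ),
            "density_descriptors.csv",
        )

        stage("markov")
        classes = markov_dynamics.discretize(
            scores, config.n_classes,
            method="explicit" if config.class_cuts else "pooled-quantile",
            cuts=config.class_cuts,
        )
        tm = markov_dynamics.transition_matrix(classes)
        save(tm.to_frame(), "transition_matrix.csv")
        if config.adjacency_csv and Path(config.adjacency_csv).exists():
            weights_sp = _read_adjacency(config.adjacency_csv, scores.units)
            lag = markov_dynamics.spatial_lag(scores, weights_sp)
            lag_classes = markov_dynamics.discretize(
                entropy_index.ScorePanel(scores.units, scores.years,
                                         np.clip(lag, 0, 1)),
                config.n_classes, method="explicit", cuts=classes.cuts,
            )
            tensor = markov_dynamics.spatial_transition_tensor(classes, lag_classes)
            save(tensor.to_frame(), "spatial_transition_tensor.csv")
        elif config.allow_partial:
            log.warning("adjacency input missing; spatial Markov stage skipped")
        else:
            raise FileNotFoundError("adjacency input required (set allow_partial to skip)")

        stage("gini")
        save(dagum_gini.gini_series(scores, partition), "gini_decomposition.csv")

        stage("panel")
        covariates = panel_io.read_covariates(config.covariates_csv)
        fits = {
            est: panel_econometrics.fit_panel(
                covariates, est, robust=config.estimator_robust
            )
            for est in ("OLS", "FE", "RE")
        }
        tests = panel_econometrics.specification_tests(
            fits["OLS"], fits["FE"], fits["RE"], covariates
        )
        rows = []
        for est, fit in fits.items():
            for name in fit.regressors:
                rows.append({"estimator": est, "variable": name,
                             "coef": fit.slope(name), "se": fit.slope_se(name),
                             "t": fit.slope(name) / fit.slope_se(name)})
            rows.append({"estimator": est, "variable": "R2", "coef": fit.r2,
                         "se": np.nan, "t": np.nan})
        rows.append({"estimator": "tests", "variable": "F_unit_effects",
                     "coef": tests.f_unit_effects, "se": np.nan,
                     "t": tests.f_unit_effects_p})
        rows.append({"estimator": "tests", "variable": "BP_LM",
                     "coef": tests.bp_lm, "se": np.nan, "t": tests.bp_lm_p})
        rows.append({"estimator": "tests", "variable": "Hausman",
                     "coef": tests.hausman, "se": np.nan, "t": tests.hausman_p})
        save(pd.DataFrame(rows), "regression.csv")

        stage("threshold")
        thr_rows = []
        for rv in config.threshold_regime_vars:
            controls = tuple(
                c for c in panel_econometrics.DEFAULT_REGRESSORS if c != rv
            )
            fit = threshold_effects.estimate_threshold(
                covariates, regime_var=rv, controls=controls,
                n_thresholds=config.threshold_n, trim=config.threshold_trim,
            )
            fit = threshold_effects.bootstrap_significance(
                covariates, fit, B=config.threshold_B, seed=config.seed
            )
            fit = threshold_effects.threshold_ci(covariates, fit)
            for i, g in enumerate(fit.thresholds):
                thr_rows.append({"regime_var": rv, "kind": f"threshold_{i + 1}",
                                 "value": g, "lo": fit.ci[i][0], "hi": fit.ci[i][1]})
            for i, c in enumerate(fit.regime_coefs):
                thr_rows.append({"regime_var": rv, "kind": f"regime_coef_{i + 1}",
                                 "value": c, "lo": np.nan, "hi": np.nan})
            for i, (f_k, p_k) in enumerate(zip(fit.f_stats, fit.boot_p)):
                thr_rows.append({"regime_var": rv, "kind": f"F_{i + 1}",
                                 "value": f_k, "lo": np.nan, "hi": p_k})
        save(pd.DataFrame(thr_rows), "thresholds.csv")
    except Exception as e:  # annotate with the failing stage context
        log.error("pipeline aborted: %s", e)
        raise

    resolved = out / "resolved_config.yaml"
    with open(resolved, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh)
    manifest = {
        "outputs": {p.name: _sha256(p) for p in artifacts},
        "seed": config.seed,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
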