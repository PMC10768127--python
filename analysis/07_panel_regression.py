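"""Drivers of supply: pooled OLS, fixed- and random-effects regression.

Regresses the composite score on lnPGDP, fiscal decentralization (FSS),
log population density, urbanization rate and tertiary-industry share,
with cluster-robust errors, and runs the F / Breusch-Pagan LM / Hausman
battery that selects among the estimators.  Writes results/regression.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phsupply import panel_econometrics, panel_io

ROOT = Path(__file__).resolve().parent.parent / "results"

cov = panel_io.read_covariates(ROOT / "inputs" / "covariates.csv")
fits = {e: panel_econometrics.fit_panel(cov, e) for e in ("OLS", "FE", "RE")}
tests = panel_econometrics.specification_tests(fits["OLS"], fits["FE"], fits["RE"], cov)

rows = []
for est, fit in fits.items():
    for name in fit.regressors:
        rows.append({"estimator": est, "variable": name, "coef": fit.slope(name),
                     "robust_se": fit.slope_se(name),
                     "t": fit.slope(name) / fit.slope_se(name)})
    rows.append({"estimator": est, "variable": "R2", "coef": fit.r2,
                 "robust_se": np.nan, "t": np.nan})
pd.DataFrame(rows).to_csv(ROOT / "regression.csv", index=False)

fe = fits["FE"]
print("fixed-effects slopes (cluster-robust t):")
for name in fe.regressors:
    print(f"  {name:>7}: {fe.slope(name):+.4f} (t={fe.slope(name)/fe.slope_se(name):+.2f})")
print(f"F(unit effects)={tests.f_unit_effects:.2f} (p={tests.f_unit_effects_p:.3g}); "
      f"BP-LM={tests.bp_lm:.2f} (p={tests.bp_lm_p:.3g}); "
      f"Hausman={tests.hausman:.2f} (p={tests.hausman_p:.3g}) -> choose {tests.choice}")
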