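"""Static panel regression of the composite score on its covariates.

Three estimators of  y_it = α_i + Σ_n δ_n x_itn + ε_it:

* pooled OLS (common intercept),
* fixed effects (within transform: OLS on unit-demeaned data),
* random effects (feasible GLS with Swamy–Arora variance components,
  i.e. quasi-demeaning by θ = 1 − sqrt(σ²_ε / (T σ²_u + σ²_ε))).

"Robust" standard errors default to cluster-robust by unit (HC1-style
heteroskedasticity-only available via ``robust="hc1"``).  The specification
battery reports the F test for joint unit-effect nullity (pooled vs FE),
the Breusch–Pagan LM test on pooled residuals (pooled vs RE), and the
Hausman test (FE vs RE) on the common slope coefficients with classical
covariances, which together select among the three estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats

from .panel_io import CovariatePanel

__all__ = ["PanelFit", "SpecTests", "fit_panel", "specification_tests"]

DEFAULT_REGRESSORS = ("lnPGDP", "FSS", "lnDEN", "UR", "ISU")


@dataclass(frozen=True)
class PanelFit:
    estimator: str                      # "OLS" | "FE" | "RE"
    regressors: tuple[str, ...]
    params: np.ndarray                  # slopes, then intercept for OLS/RE
    se: np.ndarray                      # robust (or classical if robust=None)
    classical_se: np.ndarray
    tvalues: np.ndarray
    r2: float
    nobs: int
    resid: np.ndarray
    vcov: np.ndarray                    # covariance matching ``se``
    classical_vcov: np.ndarray
    sigma2: float
    unit_effects: np.ndarray | None = None  # FE only
    intercept: float | None = None

    def slope(self, name: str) -> float:
        return float(self.params[self.regressors.index(name)])

    def slope_se(self, name: str) -> float:
        return float(self.se[self.regressors.index(name)])


@dataclass(frozen=True)
class SpecTests:
    f_unit_effects: float
    f_unit_effects_p: float
    bp_lm: float
    bp_lm_p: float
    hausman: float
    hausman_df: int
    hausman_p: float
    choice: str


def _panel_arrays(data: CovariatePanel, y_col: str, x_cols):
    f = data.frame
    y = f[y_col].to_numpy(float)
    X = f[list(x_cols)].to_numpy(float)
    unit_codes, _ = f["unit"].factorize(sort=True)
    n_units = unit_codes.max() + 1
    T = len(f) // n_units
    return y, X, unit_codes, n_units, T


def _check_rank(X: np.ndarray, names) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify an offending column by greedy elimination
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == r:
                raise ValueError(f"perfect collinearity involving column {names[j]!r}")
        raise ValueError("perfect collinearity among regressors")


def _ols(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid


def _cluster_vcov(X, resid, clusters, df_k):
    """Cluster-robust sandwich with the usual G/(G-1)·(N-1)/(N-k) correction."""
    n = len(resid)
    bread = np.linalg.inv(X.T @ X)
    groups = np.unique(clusters)
    meat = np.zeros((X.shape[1], X.shape[1]))
    for g in groups:
        idx = clusters == g
        s = X[idx].T @ resid[idx]
        meat += np.outer(s, s)
    G = len(groups)
    c = (G / (G - 1)) * ((n - 1) / (n - df_k))
    return c * bread @ meat @ bread


def _hc1_vcov(X, resid, df_k):
    n = len(resid)
    bread = np.linalg.inv(X.T @ X)
    meat = (X * resid[:, None] ** 2).T @ X
    return (n / (n - df_k)) * bread @ meat @ bread


def fit_panel(
    data: CovariatePanel,
    estimator: str = "FE",
    *,
    y_col: str = "PHS",
    x_cols=DEFAULT_REGRESSORS,
    robust: str | None = "cluster",
) -> PanelFit:
    """Fit pooled OLS, fixed-effects, or random-effects on a balanced panel."""
    estimator = estimator.upper()
    if estimator not in ("OLS", "FE", "RE"):
        raise ValueError("estimator must be 'OLS', 'FE' or 'RE'")
    if robust not in (None, "cluster", "hc1"):
        raise ValueError("robust must be None, 'cluster' or 'hc1'")
    y, X, units, n_units, T = _panel_arrays(data, y_col, x_cols)
    n, k = X.shape
    names = list(x_cols)

    if estimator == "FE":
        Xd = X - np.vstack([X[units == g].mean(axis=0) for g in range(n_units)])[units]
        yd = y - np.bincount(units, weights=y)[units] / T
        _check_rank(Xd, names)
        beta, resid = _ols(yd, Xd)
        df_k = k + n_units                      # slopes + absorbed unit means
        sigma2 = resid @ resid / (n - df_k)
        classical = sigma2 * np.linalg.inv(Xd.T @ Xd)
        if robust == "cluster":
            vcov = _cluster_vcov(Xd, resid, units, k)
        elif robust == "hc1":
            vcov = _hc1_vcov(Xd, resid, df_k)
        else:
            vcov = classical
        tss = yd @ yd
        r2 = 1.0 - (resid @ resid) / tss
        alpha = np.bincount(units, weights=y) / T - (
            np.vstack([X[units == g].mean(axis=0) for g in range(n_units)]) @ beta
        )
        se = np.sqrt(np.diag(vcov))
        return PanelFit(
            "FE", tuple(names), beta, se, np.sqrt(np.diag(classical)),
            beta / se, float(r2), n, resid, vcov, classical, float(sigma2),
            unit_effects=alpha,
        )

    if estimator == "RE":
        theta, sigma2_e, sigma2_u = _swamy_arora(y, X, units, n_units, T)
        ybar = np.bincount(units, weights=y)[units] / T
        Xbar = np.vstack([X[units == g].mean(axis=0) for g in range(n_units)])[units]
        yq = y - theta * ybar
        Xq = np.column_stack([X - theta * Xbar, np.full(n, 1.0 - theta)])
        _check_rank(Xq, names + ["const"])
        beta_full, resid = _ols(yq, Xq)
        df_k = k + 1
        s2 = resid @ resid / (n - df_k)
        classical = s2 * np.linalg.inv(Xq.T @ Xq)
        if robust == "cluster":
            vcov = _cluster_vcov(Xq, resid, units, df_k)
        elif robust == "hc1":
            vcov = _hc1_vcov(Xq, resid, df_k)
        else:
            vcov = classical
        fitted = np.column_stack([X, np.ones(n)]) @ beta_full
        r2 = np.corrcoef(fitted, y)[0, 1] ** 2
        se = np.sqrt(np.diag(vcov))
        return PanelFit(
            "RE", tuple(names), beta_full[:-1], se[:-1],
            np.sqrt(np.diag(classical))[:-1], beta_full[:-1] / se[:-1],
            float(r2), n, resid, vcov[:-1, :-1], classical[:-1, :-1],
            float(sigma2_e), intercept=float(beta_full[-1]),
        )

    # pooled OLS
    Xc = np.column_stack([X, np.ones(n)])
    _check_rank(Xc, names + ["const"])
    beta_full, resid = _ols(y, Xc)
    df_k = k + 1
    s2 = resid @ resid / (n - df_k)
    classical = s2 * np.linalg.inv(Xc.T @ Xc)
    if robust == "cluster":
        vcov = _cluster_vcov(Xc, resid, units, df_k)
    elif robust == "hc1":
        vcov = _hc1_vcov(Xc, resid, df_k)
    else:
        vcov = classical
    r2 = 1.0 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
    se = np.sqrt(np.diag(vcov))
    return PanelFit(
        "OLS", tuple(names), beta_full[:-1], se[:-1],
        np.sqrt(np.diag(classical))[:-1], beta_full[:-1] / se[:-1],
        float(r2), n, resid, vcov[:-1, :-1], classical[:-1, :-1], float(s2),
        intercept=float(beta_full[-1]),
    )


def _swamy_arora(y, X, units, n_units, T):
    """Swamy–Arora variance components from within and between regressions."""
    n, k = X.shape
    Xd = X - np.vstack([X[units == g].mean(axis=0) for g in range(n_units)])[units]
    yd = y - np.bincount(units, weights=y)[units] / T
    _, resid_w = _ols(yd, Xd)
    sigma2_e = resid_w @ resid_w / (n - n_units - k)
    ybar = np.bincount(units, weights=y) / T
    Xbar = np.vstack([X[units == g].mean(axis=0) for g in range(n_units)])
    Xbar_c = np.column_stack([Xbar, np.ones(n_units)])
    _, resid_b = _ols(ybar, Xbar_c)
    sigma2_between = resid_b @ resid_b / max(n_units - k - 1, 1)
    sigma2_u = max(sigma2_between - sigma2_e / T, 0.0)
    theta = 1.0 - np.sqrt(sigma2_e / (T * sigma2_u + sigma2_e))
    return theta, sigma2_e, sigma2_u


def specification_tests(
    ols: PanelFit, fe: PanelFit, re: PanelFit, data: CovariatePanel,
    *, y_col: str = "PHS",
) -> SpecTests:
    """F (unit effects), Breusch–Pagan LM, and Hausman tests.

    The Hausman statistic uses the classical covariances of FE and RE (a
    robust Hausman is not well defined); a non-positive-definite covariance
    difference falls back to the Moore–Penrose pseudo-inverse with a warning.
    """
    if ols.regressors != fe.regressors or fe.regressors != re.regressors:
        raise ValueError("fits must share the regressor set")
    y, X, units, n_units, T = _panel_arrays(data, y_col, list(fe.regressors))
    n, k = X.shape

    ssr_pooled = ols.resid @ ols.resid
    ssr_fe = fe.resid @ fe.resid
    df1, df2 = n_units - 1, n - n_units - k
    f_stat = ((ssr_pooled - ssr_fe) / df1) / (ssr_fe / df2)
    f_p = stats.f.sf(f_stat, df1, df2)

    # Breusch–Pagan LM for random effects, balanced-panel form
    e = ols.resid
    unit_sums = np.bincount(units, weights=e)
    lm = (n_units * T / (2.0 * (T - 1))) * ((unit_sums @ unit_sums) / (e @ e) - 1.0) ** 2
    lm_p = stats.chi2.sf(lm, 1)

    # Hausman with a common sigma^2 (from the efficient model's residuals) in
    # both covariances; the within moment matrix is then dominated by the
    # quasi-demeaned one, so the difference is positive semidefinite by
    # construction rather than by luck of two separate variance estimates.
    diff = fe.params - re.params
    Xd = X - np.vstack([X[units == g].mean(axis=0) for g in range(n_units)])[units]
    theta, _, _ = _swamy_arora(y, X, units, n_units, T)
    Xbar = np.vstack([X[units == g].mean(axis=0) for g in range(n_units)])[units]
    Xq = np.column_stack([X - theta * Xbar, np.full(n, 1.0 - theta)])
    s2 = re.resid @ re.resid / (n - k - 1)
    v_fe = np.linalg.inv(Xd.T @ Xd)
    v_re = np.linalg.inv(Xq.T @ Xq)[:k, :k]
    vdiff = s2 * (v_fe - v_re)
    try:
        h = float(diff @ np.linalg.solve(vdiff, diff))
        if h < 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn(
            "Hausman covariance difference not positive definite; "
            "using pseudo-inverse", stacklevel=2,
        )
        h = abs(float(diff @ np.linalg.pinv(vdiff) @ diff))
    h_p = stats.chi2.sf(h, k)

    if f_p < 0.05 or lm_p < 0.05:
        choice = "FE" if h_p < 0.05 else "RE"
    else:
        choice = "OLS"
    return SpecTests(
        float(f_stat), float(f_p), float(lm), float(lm_p), h, k, float(h_p), choice
    )
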