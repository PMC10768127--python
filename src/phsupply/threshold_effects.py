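"""Fixed-effects panel threshold regression (Hansen-style).

The model lets the slope on a regime variable x (urbanization rate or fiscal
decentralization) jump when a threshold variable q (lnPGDP) crosses unknown
cut points γ:

    y_it = μ_i + β_1 x_it·I(q_it ≤ γ) + β_2 x_it·I(q_it > γ) + δ'c_it + ε_it

and analogously with two or three thresholds (one regime slope per segment).
Estimation is by concentrated least squares: for each candidate γ on the
trimmed grid of observed q values the model is within-demeaned and fit by
OLS; γ̂ minimizes the SSR.  Multiple thresholds are found sequentially with
one back-refinement of the first after the second is located.

Significance of the k-th threshold uses F_k = (SSR_{k−1} − SSR_k)/σ̂² with a
residual-bootstrap null distribution (data regenerated from the (k−1)-
threshold fit), and the 95% threshold confidence set inverts the likelihood
ratio LR(γ) = (SSR(γ) − SSR(γ̂))/σ̂² at Hansen's critical value
c = −2·ln(1 − sqrt(level)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .panel_io import CovariatePanel

__all__ = ["ThresholdFit", "estimate_threshold", "bootstrap_significance", "threshold_ci"]

# the threshold variable's own level effect stays in the model as a control
DEFAULT_CONTROLS = ("lnPGDP", "lnDEN", "ISU")


@dataclass(frozen=True)
class ThresholdFit:
    regime_var: str
    threshold_var: str
    controls: tuple[str, ...]
    thresholds: tuple[float, ...]           # sorted ascending
    regime_coefs: np.ndarray                # one slope per regime (thresholds+1)
    regime_se: np.ndarray
    control_coefs: np.ndarray
    control_se: np.ndarray
    ssr: float
    ssr_by_k: tuple[float, ...]             # SSR with 0..m thresholds
    sigma2: float
    r2: float
    nobs: int
    grid: np.ndarray
    f_stats: tuple[float, ...] | None = None
    boot_p: tuple[float, ...] | None = None
    n_boot: int | None = None
    ci: tuple[tuple[float, float], ...] | None = None

    @property
    def n_regimes(self) -> int:
        return len(self.thresholds) + 1


class _Problem:
    """Cached arrays for one threshold-regression data set."""

    def __init__(self, data: CovariatePanel, y_col, regime_var, threshold_var, controls):
        f = data.frame
        self.y = f[y_col].to_numpy(float)
        self.xr = f[regime_var].to_numpy(float)
        self.q = f[threshold_var].to_numpy(float)
        self.C = f[list(controls)].to_numpy(float) if controls else np.empty((len(f), 0))
        codes, _ = f["unit"].factorize(sort=True)
        self.units = codes
        self.n_units = codes.max() + 1
        self.n = len(f)
        self.T = self.n // self.n_units
        self.yd = self._demean(self.y)
        self.Cd = self._demean(self.C)

    def _demean(self, a):
        a = np.asarray(a, float)
        squeeze = a.ndim == 1
        if squeeze:
            a = a[:, None]
        sums = np.zeros((self.n_units, a.shape[1]))
        np.add.at(sums, self.units, a)
        out = a - (sums / self.T)[self.units]
        return out[:, 0] if squeeze else out

    def design(self, thresholds) -> np.ndarray:
        """Within-demeaned regressors: regime-split slopes then controls."""
        edges = [-np.inf, *sorted(thresholds), np.inf]
        cols = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            cols.append(self.xr * ((self.q > lo) & (self.q <= hi)))
        X = np.column_stack(cols)
        return np.column_stack([self._demean(X), self.Cd])

    def regime_counts(self, thresholds) -> np.ndarray:
        edges = [-np.inf, *sorted(thresholds), np.inf]
        return np.array(
            [np.sum((self.q > lo) & (self.q <= hi)) for lo, hi in zip(edges[:-1], edges[1:])]
        )

    def ssr(self, thresholds, y_demeaned=None) -> float:
        yd = self.yd if y_demeaned is None else y_demeaned
        X = self.design(thresholds)
        beta, *_ = np.linalg.lstsq(X, yd, rcond=None)
        r = yd - X @ beta
        return float(r @ r)

    def fit(self, thresholds):
        X = self.design(thresholds)
        beta, *_ = np.linalg.lstsq(X, self.yd, rcond=None)
        resid = self.yd - X @ beta
        ssr = float(resid @ resid)
        k = X.shape[1]
        dof = self.n - self.n_units - k
        sigma2 = ssr / dof
        vcov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(vcov))
        return beta, se, resid, ssr, sigma2


def _candidate_grid(q: np.ndarray, trim: float, max_grid: int) -> np.ndarray:
    qs = np.unique(q)
    lo, hi = np.quantile(q, [trim, 1.0 - trim])
    grid = qs[(qs >= lo) & (qs <= hi)]
    if len(grid) > max_grid:
        grid = np.quantile(grid, np.linspace(0, 1, max_grid))
        grid = np.unique(grid)
    return grid


def _search(prob: _Problem, grid, fixed, min_obs, y_demeaned=None):
    """Best additional threshold given the already-fixed ones."""
    best_g, best_ssr = None, np.inf
    for g in grid:
        if any(abs(g - f) < 1e-12 for f in fixed):
            continue
        cand = sorted([*fixed, g])
        if prob.regime_counts(cand).min() < min_obs:
            continue
        s = prob.ssr(cand, y_demeaned)
        if s < best_ssr:
            best_g, best_ssr = g, s
    if best_g is None:
        raise ValueError("no admissible threshold candidate survives the trim/size rules")
    return best_g, best_ssr


def _sequential_thresholds(prob, grid, n_thresholds, min_obs, y_demeaned=None):
    """Sequential estimation with one back-refinement of the first threshold."""
    g1, _ = _search(prob, grid, [], min_obs, y_demeaned)
    found = [g1]
    if n_thresholds >= 2:
        g2, _ = _search(prob, grid, [g1], min_obs, y_demeaned)
        g1r, _ = _search(prob, grid, [g2], min_obs, y_demeaned)
        found = [g1r, g2]
    if n_thresholds == 3:
        g3, _ = _search(prob, grid, found, min_obs, y_demeaned)
        found.append(g3)
    return tuple(sorted(found))


def estimate_threshold(
    data: CovariatePanel,
    regime_var: str = "UR",
    threshold_var: str = "lnPGDP",
    controls=DEFAULT_CONTROLS,
    n_thresholds: int = 2,
    *,
    y_col: str = "PHS",
    trim: float = 0.01,
    max_grid: int = 100,
) -> ThresholdFit:
    """Grid-search threshold estimation on the within-transformed panel."""
    if n_thresholds not in (1, 2, 3):
        raise ValueError("n_thresholds must be 1, 2 or 3")
    prob = _Problem(data, y_col, regime_var, threshold_var, controls)
    grid = _candidate_grid(prob.q, trim, max_grid)
    k_full = n_thresholds + 1 + prob.C.shape[1]
    min_obs = max(k_full, 2)

    ssr_by_k = [prob.ssr([])]
    thresholds: tuple[float, ...] = ()
    for m in range(1, n_thresholds + 1):
        thresholds = _sequential_thresholds(prob, grid, m, min_obs)
        ssr_by_k.append(prob.ssr(thresholds))

    beta, se, resid, ssr, sigma2 = prob.fit(thresholds)
    n_reg = len(thresholds) + 1
    tss = prob.yd @ prob.yd
    return ThresholdFit(
        regime_var, threshold_var, tuple(controls), thresholds,
        beta[:n_reg], se[:n_reg], beta[n_reg:], se[n_reg:],
        ssr, tuple(ssr_by_k), sigma2, float(1.0 - ssr / tss), prob.n, grid,
    )


def bootstrap_significance(
    data: CovariatePanel,
    fit: ThresholdFit,
    B: int = 300,
    seed: int | None = None,
    *,
    y_col: str = "PHS",
) -> ThresholdFit:
    """Bootstrap F tests for each added threshold.

    For the k-th threshold the null model has k−1 thresholds (re-estimated on
    every bootstrap sample); bootstrap data are the null fitted values plus
    i.i.d. resampled within-residuals.  Returns a copy of ``fit`` carrying
    ``f_stats`` and ``boot_p``.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    prob = _Problem(data, y_col, fit.regime_var, fit.threshold_var, fit.controls)
    grid = fit.grid
    m = len(fit.thresholds)
    min_obs = max(m + 1 + prob.C.shape[1], 2)

    f_stats, pvals = [], []
    for k in range(1, m + 1):
        ssr_null, ssr_alt = fit.ssr_by_k[k - 1], fit.ssr_by_k[k]
        k_params = k + 1 + prob.C.shape[1]
        sigma2 = ssr_alt / (prob.n - prob.n_units - k_params)
        f_obs = (ssr_null - ssr_alt) / sigma2
        f_stats.append(float(f_obs))

        # null fit with k-1 thresholds
        if k == 1:
            null_thr: tuple[float, ...] = ()
        else:
            null_thr = _sequential_thresholds(prob, grid, k - 1, min_obs)
        Xn = prob.design(null_thr)
        beta_n, *_ = np.linalg.lstsq(Xn, prob.yd, rcond=None)
        fitted = Xn @ beta_n
        resid = prob.yd - fitted

        exceed = 0
        for _ in range(B):
            y_star = fitted + rng.choice(resid, size=prob.n, replace=True)
            y_star = prob._demean(y_star)       # stay in the within-transformed space
            if k == 1:
                ssr0 = prob.ssr([], y_star)
            else:
                thr0 = _sequential_thresholds(prob, grid, k - 1, min_obs, y_star)
                ssr0 = prob.ssr(thr0, y_star)
            thr1 = _sequential_thresholds(prob, grid, k, min_obs, y_star)
            ssr1 = prob.ssr(thr1, y_star)
            sigma2_b = ssr1 / (prob.n - prob.n_units - k_params)
            if (ssr0 - ssr1) / sigma2_b >= f_obs:
                exceed += 1
        pvals.append(exceed / B)
    return replace(fit, f_stats=tuple(f_stats), boot_p=tuple(pvals), n_boot=B)


def threshold_ci(
    data: CovariatePanel,
    fit: ThresholdFit,
    level: float = 0.95,
    *,
    y_col: str = "PHS",
) -> ThresholdFit:
    """Likelihood-ratio confidence set per threshold.

    LR(γ) = (SSR(γ) − SSR(γ̂))/σ̂² profiled over the grid with the other
    thresholds held at their estimates; the interval is the range of grid
    points with LR ≤ −2·ln(1 − sqrt(level)).  Always contains γ̂.
    """
    crit = -2.0 * np.log(1.0 - np.sqrt(level))
    prob = _Problem(data, y_col, fit.regime_var, fit.threshold_var, fit.controls)
    intervals = []
    for j, g_hat in enumerate(fit.thresholds):
        others = [g for i, g in enumerate(fit.thresholds) if i != j]
        ssr_hat = fit.ssr
        lo = hi = g_hat
        for g in fit.grid:
            cand = sorted([*others, g])
            lr = (prob.ssr(cand) - ssr_hat) / fit.sigma2
            if lr <= crit:
                lo, hi = min(lo, g), max(hi, g)
        intervals.append((float(lo), float(hi)))
    return replace(fit, ci=tuple(intervals))
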