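"""Partial least squares regression linking reaction fluxes to insulin.

The flux table (conditions x reactions, time-averaged fluxes in mM/min)
is regressed against measured insulin-secretion fold changes with the
SIMPLS algorithm.  Inputs are autoscaled (zero mean, unit variance per
column), the response is centered.  Reported quantities:

* regression coefficients (standardized and raw scale),
* VIP scores — variable importance in projection; the mean of squared
  VIPs is exactly 1 and columns with VIP > 1 are deemed influential,
* R^2 (goodness of fit) and leave-one-out Q^2Y (goodness of
  prediction, scaling re-estimated inside every fold).

With a single response variable SIMPLS coincides with PLS1; the tests
cross-check coefficients against an independent deflation-free oracle
and scikit-learn's NIPALS implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PLSRFit:
    """Fitted SIMPLS model (univariate response)."""

    n_components: int
    columns: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    weights: np.ndarray      # (p, A) SIMPLS weight vectors (x_std space)
    x_loadings: np.ndarray   # (p, A)
    scores: np.ndarray       # (n, A) orthonormal
    y_loadings: np.ndarray   # (A,)
    coef_std: np.ndarray     # (p,) coefficients in autoscaled space
    r2: float
    dropped: list[str] = field(default_factory=list)

    @property
    def coef_raw(self) -> np.ndarray:
        """Coefficients applicable to raw (unscaled) flux values."""
        return self.coef_std / self.x_std

    @property
    def intercept(self) -> float:
        return self.y_mean - float(np.dot(self.x_mean, self.coef_raw))

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.columns):
            raise ValueError(
                f"flux vector has {X.shape[1]} entries, model expects {len(self.columns)}"
            )
        return X @ self.coef_raw + self.intercept

    def vip(self) -> np.ndarray:
        return vip_scores(self)

    def explained_y_variance(self) -> np.ndarray:
        """Per-component share of the response variance (training)."""
        ssy = self.y_loadings ** 2
        total = ssy.sum()
        return ssy / total if total > 0 else ssy


def _autoscale(X: np.ndarray):
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    return mean, std


def simpls_fit(X: np.ndarray | pd.DataFrame, y: np.ndarray | pd.Series,
               n_components: int = 3) -> PLSRFit:
    """Fit a univariate-response PLSR model with the SIMPLS algorithm.

    ``X`` is autoscaled and ``y`` centered internally.  Zero-variance
    columns are dropped with a warning (their coefficients and VIPs are
    reported as zero).  Requesting more components than the data's rank
    raises.
    """
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("response length does not match the flux table rows")
    if n < 2:
        raise ValueError("need at least two rows")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, columns)={min(n - 1, p)}"
        )

    mean, std = _autoscale(X)
    keep = std > 0
    dropped = [c for c, k in zip(columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    std_safe = np.where(keep, std, 1.0)
    X0 = (X - mean) / std_safe
    X0 = X0[:, keep]
    y_mean = float(y.mean())
    y0 = y - y_mean
    p_eff = int(keep.sum())
    if n_components > p_eff:
        raise ValueError("rank deficiency: fewer informative columns than components")

    S = X0.T @ y0
    S0_norm = np.linalg.norm(S)
    W = np.zeros((p_eff, n_components))
    P = np.zeros((p_eff, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    V = np.zeros((p_eff, n_components))
    n_used = n_components
    for a in range(n_components):
        if np.linalg.norm(S) < 1e-10 * max(S0_norm, 1.0):
            # response variance exhausted: truncate rather than fail
            warnings.warn(f"response exhausted after {a} components; truncating")
            n_used = a
            break
        r = S.copy()
        t = X0 @ r
        t -= t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            raise ValueError(f"rank deficiency at component {a + 1}")
        t /= normt
        r /= normt
        pa = X0.T @ t
        qa = float(y0 @ t)
        v = pa.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pa)
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValueError(f"rank deficiency at component {a + 1}")
        v /= nv
        S = S - v * (v @ S)
        W[:, a], P[:, a], T[:, a], q[a], V[:, a] = r, pa, t, qa, v
    W, P, T, q, V = W[:, :n_used], P[:, :n_used], T[:, :n_used], q[:n_used], V[:, :n_used]

    coef_eff = W @ q
    coef_std = np.zeros(p)
    coef_std[keep] = coef_eff

    weights = np.zeros((p, n_used)); weights[keep] = W
    loadings = np.zeros((p, n_used)); loadings[keep] = P

    y_hat = X0 @ coef_eff + y_mean
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y_mean) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    return PLSRFit(n_components=n_used, columns=columns,
                   x_mean=mean, x_std=std_safe, y_mean=y_mean,
                   weights=weights, x_loadings=loadings, scores=T,
                   y_loadings=q, coef_std=coef_std, r2=r2, dropped=dropped)


def vip_scores(fit: PLSRFit) -> np.ndarray:
    """Variable importance in projection.

    ``VIP_j = sqrt(p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a)``
    with ``SSY_a`` the response variance explained by component ``a``.
    The mean of the squared VIPs equals 1 exactly.
    """
    W = fit.weights
    ssy = fit.y_loadings ** 2
    p = W.shape[0]
    norms = np.linalg.norm(W, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    frac = (W / norms) ** 2
    denom = ssy.sum()
    if denom == 0:
        return np.zeros(p)
    return np.sqrt(p * (frac @ ssy) / denom)


def q2y_loo(X: np.ndarray | pd.DataFrame, y: np.ndarray | pd.Series,
            n_components: int = 3) -> float:
    """Leave-one-out cross-validated Q^2Y.

    ``Q2Y = 1 - PRESS / TSS`` with TSS about the full-sample mean and
    the autoscaling re-estimated inside each fold.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    n = Xa.shape[0]
    if n < 3:
        raise ValueError("need at least three rows for leave-one-out validation")
    if n - 1 < n_components + 1:
        raise ValueError(f"too few rows ({n}) for {n_components} components in LOO folds")
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        fit = simpls_fit(Xa[mask], ya[mask], n_components)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = float(fit.predict(Xa[i: i + 1])[0])
        press += (pred - ya[i]) ** 2
    tss = float(((ya - ya.mean()) ** 2).sum())
    return 1.0 - press / tss


def predict_insulin(fit, flux_vector) -> float:
    """Predicted insulin fold change for a flux vector.

    ``fit`` may be a single :class:`PLSRFit` or a sequence (ensemble) of
    fits, in which case the arithmetic mean of the per-model predictions
    is returned (the convention used for the eight best-fit parameter
    sets).
    """
    x = np.asarray(flux_vector, dtype=float).reshape(1, -1)
    if isinstance(fit, PLSRFit):
        return float(fit.predict(x)[0])
    preds = [float(f.predict(x)[0]) for f in fit]
    return float(np.mean(preds))


def timecourse_plsr(per_minute_fluxes: pd.DataFrame, insulin_fc_total: float,
                    duration: float, n_components: int = 3) -> PLSRFit:
    """Time-resolved PLSR over a single short stimulation course.

    Rows of ``per_minute_fluxes`` are the per-minute average fluxes of
    minutes ``1..T``.  The response assumes a linear rise of secreted
    insulin: at minute ``m`` the fold change is
    ``1 + (FC_total - 1) * m / T`` (equal to ``FC_total`` at ``m = T``).
    When the course is too short for the requested components the count
    is reduced with a warning.
    """
    T = int(duration)
    X = per_minute_fluxes.iloc[:T]
    if X.shape[0] != T:
        raise ValueError(f"need {T} per-minute rows, got {X.shape[0]}")
    minutes = np.arange(1, T + 1)
    y = 1.0 + (insulin_fc_total - 1.0) * minutes / T
    max_comp = T - 1
    if n_components > max_comp:
        warnings.warn(
            f"{T}-minute course supports at most {max_comp} components; reducing"
        )
        n_components = max_comp
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simpls_fit(X, y, n_components)


# ---------------------------------------------------------------------------
# model-style front door


class FluxInsulinPLS:
    """PLSR model of insulin secretion from time-averaged fluxes.

    Parameters
    ----------
    flux_table : DataFrame
        Conditions (stimulation durations, minutes) x reactions.
    insulin : Series or array
        Insulin-secretion fold change per condition (16.7 vs 2.8 mM).
    n_components : int
        PLSR components (default 3, following the variance profile of
        the fitted ensemble).
    train_times : tuple
        Rows used for training; the remaining rows are validation.
    """

    def __init__(self, flux_table: pd.DataFrame, insulin, n_components: int = 3,
                 train_times: tuple = (3.0, 15.0, 60.0)):
        self.flux_table = flux_table
        self.insulin = pd.Series(np.asarray(insulin, dtype=float).ravel(),
                                 index=flux_table.index)
        if (self.insulin <= 0).any():
            raise ValueError("insulin fold changes must be positive")
        self.n_components = n_components
        self.train_times = tuple(float(t) for t in train_times)

    def fit(self) -> "PLSResults":
        train_idx = [t for t in self.flux_table.index if float(t) in self.train_times]
        if len(train_idx) < 2:
            raise ValueError("fewer than two training rows")
        Xtr = self.flux_table.loc[train_idx]
        ytr = self.insulin.loc[train_idx]
        ncomp = min(self.n_components, len(train_idx) - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = simpls_fit(Xtr, ytr, ncomp)
        return PLSResults(self, fit)


class PLSResults:
    """Fitted flux->insulin regression with importance diagnostics."""

    def __init__(self, model: FluxInsulinPLS, fit: PLSRFit):
        self.model = model
        self.fit = fit

    @property
    def vip(self) -> pd.Series:
        return pd.Series(vip_scores(self.fit), index=self.fit.columns, name="VIP")

    @property
    def weights(self) -> pd.Series:
        """Standardized regression coefficients (sign = direction of effect)."""
        return pd.Series(self.fit.coef_std, index=self.fit.columns, name="weight")

    @property
    def r2(self) -> float:
        return self.fit.r2

    def influential(self) -> pd.DataFrame:
        """Reactions with VIP > 1, ascending (heat-bar convention)."""
        df = pd.DataFrame({"VIP": self.vip, "weight": self.weights})
        return df[df.VIP > 1].sort_values("VIP")

    def predict(self, flux_vector) -> float:
        return predict_insulin(self.fit, flux_vector)

    def q2y(self) -> float:
        """Leave-one-out Q^2Y over *all* available conditions."""
        return q2y_loo(self.model.flux_table, self.model.insulin, self.fit.n_components)

    def summary(self) -> str:
        infl = self.influential()
        lines = [
            "Flux -> insulin PLSR (SIMPLS)",
            "=============================",
            f"components : {self.fit.n_components}",
            f"rows (train): {len(self.model.train_times)} of {len(self.model.flux_table)}",
            f"R^2        : {self.fit.r2:.4f}",
            f"Q^2Y (LOO) : {self.q2y():.4f}",
            f"influential (VIP > 1): {len(infl)} of {len(self.fit.columns)}",
            "",
            "reaction        VIP     weight",
        ]
        for rid, row in infl.iloc[::-1].iterrows():
            lines.append(f"{rid:12s} {row.VIP:7.3f} {row.weight:+9.4f}")
        return "\n".join(lines)


def fit_ensemble(flux_tables: list[pd.DataFrame], insulin, n_components: int = 3,
                 train_times: tuple = (3.0, 15.0, 60.0)) -> list[PLSResults]:
    """One PLSR model per fitted parameter set's flux table."""
    return [FluxInsulinPLS(tab, insulin, n_components, train_times).fit()
            for tab in flux_tables]
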