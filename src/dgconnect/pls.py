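"""Univariate-response partial least squares regression (PLS1) and the VIP statistic.

The connectivity analysis regresses one seed region's uptake on all other
regions.  With more predictors (48) than animals (10) ordinary least squares
is undefined, so the field uses PLS: predictors are projected onto a small
number of latent components chosen to maximise covariance with the response.
A predictor's overall contribution across components is summarised by the
variable-importance-in-projection (VIP) statistic,

    VIP_j = sqrt( p * sum_a SS_a * w_{ja}^2 / sum_a SS_a ),

where ``p`` is the number of predictors, ``w_a`` the unit-norm weight vector
of component ``a`` and ``SS_a = q_a^2 (t_a' t_a)`` the response sum of squares
explained by that component.  The normalisation forces mean(VIP^2) = 1, so
VIP ~ 1 marks an "average" contribution and values above ~0.8 a considerable
one.

Both predictors and response are mean-centred and scaled to unit variance
(sample SD, ddof=1) before fitting — the chemometrics convention.  VIP is not
scale-invariant, so this choice is fixed and recorded here.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._base import BaseEstimator, check_fitted
from .exceptions import ConfigurationError, DegenerateDataError

__all__ = ["PLS1Regression", "fit_plsr", "vip", "choose_ncomp"]

_EPS = 1e-12


def _pls1_core(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS for a single response on pre-centred/scaled data.

    For univariate y each component's weight has the closed form
    w_a = X_a' y_a / ||X_a' y_a|| on the deflated data, so no inner iteration
    is needed.  Returns (W, T, P, q, ss) truncated to the components actually
    extracted (extraction stops early once the residual response is exhausted).
    """
    n, p = X.shape
    W = np.empty((p, n_components))
    T = np.empty((n, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    ss = np.empty(n_components)

    Xd = np.array(X, dtype=float, copy=True)
    yd = np.array(y, dtype=float, copy=True).ravel()
    y_scale = max(float(np.linalg.norm(yd)), 1.0)

    used = 0
    for a in range(n_components):
        w = Xd.T @ yd
        wn = float(np.linalg.norm(w))
        if wn <= _EPS * y_scale:
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        pa = (Xd.T @ t) / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pa)
        yd -= qa * t
        W[:, a] = w
        T[:, a] = t
        P[:, a] = pa
        q[a] = qa
        ss[a] = qa * qa * tt
        used += 1

    return W[:, :used], T[:, :used], P[:, :used], q[:used], ss[:used]


def _standardize(M: np.ndarray):
    """Centre columns; scale non-constant columns to unit sample SD.

    Constant columns are mapped to exactly zero (their centred values), which
    keeps them inert in the fit without producing NaNs — the caller decides
    whether to drop or tolerate them.
    """
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    scale = np.where(sd > 0, sd, 1.0)
    return (M - mean) / scale, mean, sd, scale


def vip_from_fit(W: np.ndarray, ss: np.ndarray) -> np.ndarray:
    """VIP vector from unit-norm weights and per-component explained response SS."""
    total = float(ss.sum())
    if W.shape[1] == 0 or total <= 0:
        raise DegenerateDataError(
            "response carries no variance explainable by the predictors; VIP undefined"
        )
    p = W.shape[0]
    return np.sqrt(p * (W**2 @ ss) / total)


class PLS1Regression(BaseEstimator):
    """PLS regression with a single response and NIPALS deflation.

    Parameters
    ----------
    n_components : int, default 2
        Number of latent components ``A``.  Must satisfy
        ``A <= min(n_samples - 1, n_predictors)``.
    scale : bool, default True
        Standardise predictors and response to unit sample SD before fitting.
        The VIP statistic assumes this; disable only for diagnostics.
    drop_constant : bool, default True
        Drop constant predictor columns with a warning instead of failing.

    Attributes
    ----------
    x_weights_ : (p_kept, A) array — unit-norm weight vectors ``w_a``.
    x_scores_ : (n, A) array — score vectors ``t_a`` (mutually orthogonal).
    x_loadings_ : (p_kept, A) array — predictor loadings ``p_a``.
    y_loadings_ : (A,) array — response loadings ``q_a``.
    explained_ss_ : (A,) array — per-component explained response SS (scaled units).
    vip_ : (p_kept,) array — VIP statistic per retained predictor.
    coef_ : (p_kept,) array — regression coefficients in original units.
    intercept_ : float
    kept_mask_ : (p,) bool array — predictors retained after constant-column dropping.
    n_components_ : int — components actually extracted (may be < n_components
        when the response is exhausted early).
    """

    def __init__(self, n_components: int = 2, scale: bool = True, drop_constant: bool = True):
        self.n_components = n_components
        self.scale = scale
        self.drop_constant = drop_constant

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ConfigurationError("X must be a 2-D animals x predictors matrix")
        n, p = X.shape
        if y.shape[0] != n:
            raise ConfigurationError(f"X has {n} rows but y has {y.shape[0]} values")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ConfigurationError("X and y must be finite with no missing values")

        sd = X.std(axis=0, ddof=1)
        kept = sd > 0
        if not kept.all():
            if not self.drop_constant:
                raise DegenerateDataError("constant predictor column(s) present")
            dropped = [int(i) for i in np.flatnonzero(~kept)]
            warnings.warn(
                f"dropping {len(dropped)} constant predictor column(s): {dropped}",
                UserWarning,
                stacklevel=2,
            )
        Xk = X[:, kept]
        p_kept = Xk.shape[1]
        if p_kept == 0:
            raise DegenerateDataError("all predictor columns are constant")

        max_a = min(n - 1, p_kept)
        if not (1 <= self.n_components <= max_a):
            raise ConfigurationError(
                f"n_components={self.n_components} invalid; must be in [1, {max_a}] "
                f"for {n} samples and {p_kept} usable predictors"
            )

        if self.scale:
            Xs, x_mean, _, x_scale = _standardize(Xk)
            y_sd = y.std(ddof=1)
            y_scale = y_sd if y_sd > 0 else 1.0
        else:
            x_mean = Xk.mean(axis=0)
            x_scale = np.ones(p_kept)
            Xs = Xk - x_mean
            y_scale = 1.0
        y_mean = y.mean()
        ys = (y - y_mean) / y_scale

        W, T, P, q, ss = _pls1_core(Xs, ys, self.n_components)
        if W.shape[1] == 0:
            raise DegenerateDataError("response is orthogonal to all predictors")

        self.x_weights_ = W
        self.x_scores_ = T
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.explained_ss_ = ss
        self.n_components_ = W.shape[1]
        self.kept_mask_ = kept
        self.x_mean_ = x_mean
        self.x_scale_ = x_scale
        self.y_mean_ = y_mean
        self.y_scale_ = y_scale
        self.vip_ = vip_from_fit(W, ss)

        # b = W (P'W)^{-1} q maps scaled X to scaled y in one shot
        b_scaled = W @ np.linalg.solve(P.T @ W, q)
        self.coef_ = b_scaled * y_scale / x_scale
        self.intercept_ = float(y_mean - Xk.mean(axis=0) @ self.coef_)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ConfigurationError(
                f"X must have {self.n_features_in_} columns (got shape {X.shape})"
            )
        return X[:, self.kept_mask_] @ self.coef_ + self.intercept_

    def score(self, X, y):
        """Coefficient of determination R^2 on (X, y)."""
        y = np.asarray(y, dtype=float).ravel()
        resid = y - self.predict(X)
        total = y - y.mean()
        return 1.0 - float(resid @ resid) / float(total @ total)


def fit_plsr(X, y, n_components: int = 2, **kwargs) -> PLS1Regression:
    """Fit a :class:`PLS1Regression`; thin functional wrapper."""
    return PLS1Regression(n_components=n_components, **kwargs).fit(X, y)


def vip(model: PLS1Regression) -> np.ndarray:
    """VIP vector of a fitted model (one value per retained predictor)."""
    check_fitted(model, "vip_")
    return model.vip_


def choose_ncomp(X, y, max_components: int) -> int:
    """Pick the component count by leave-one-out CV with the one-SE rule.

    Computes the LOO squared prediction error for A = 1..max_components and
    returns the smallest A whose mean error is within one standard error of
    the minimum.  Deterministic; the original connectivity protocol does not
    state A, so this gives a principled, reproducible default.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 4:
        raise ConfigurationError("leave-one-out component selection needs n >= 4 animals")
    max_a = min(max_components, n - 2, X.shape[1])
    if max_a < 1:
        raise ConfigurationError("max_components leaves no admissible component count")

    sq_errors = np.empty((max_a, n))
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        model = PLS1Regression(n_components=max_a).fit(X[mask], y[mask])
        # one fit at max_a gives predictions for every smaller A by truncation
        Xs = (X[i : i + 1, model.kept_mask_] - model.x_mean_) / np.where(
            model.x_scale_ > 0, model.x_scale_, 1.0
        )
        W, P, q = model.x_weights_, model.x_loadings_, model.y_loadings_
        a_used = model.n_components_
        preds = np.full(max_a, np.nan)
        for a in range(1, a_used + 1):
            b = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
            preds[a - 1] = model.y_mean_ + model.y_scale_ * float((Xs @ b)[0])
        if a_used < max_a:  # exhausted response: prediction stops improving
            preds[a_used:] = preds[a_used - 1]
        sq_errors[:, i] = (y[i] - preds) ** 2

    mean_err = sq_errors.mean(axis=1)
    se_err = sq_errors.std(axis=1, ddof=1) / np.sqrt(n)
    best = int(np.argmin(mean_err))
    # relative floor keeps the rule scale-free when CV errors are ~0 (noiseless data)
    threshold = mean_err[best] + se_err[best] + 1e-8 * float(np.var(y))
    return int(np.flatnonzero(mean_err <= threshold)[0]) + 1
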