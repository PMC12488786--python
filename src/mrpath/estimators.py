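"""Scikit-learn-style estimators for summary-data Mendelian randomization.

Each estimator regresses per-variant outcome effects ``y = beta_y`` on one or
more columns of exposure effects ``X = beta_x`` with inverse-variance weights
``1 / se_y**2``, following the standard equivalence between the
inverse-variance-weighted (IVW) meta-analysis of Wald ratios and weighted
zero-intercept regression.  All estimators expose the sklearn contract:
``fit(X, y, se_y=...)``, ``get_params`` / ``set_params``, fitted attributes
with a trailing underscore, and compose with sklearn model-selection
utilities.  ``coef_`` is the per-exposure causal estimate (log-odds of a
binary outcome per unit of exposure); with a single column these are the
univariable estimators, with several they are their multivariable (MVMR)
generalizations.

Inference uses normal critical values throughout (95% intervals at 1.96) and
a multiplicative over-dispersion model for heterogeneity: standard errors are
scaled by ``max(1, sqrt(Q / df))`` under ``model="random"`` and never shrink
below the fixed-effects value.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "IVWEstimator",
    "EggerEstimator",
    "WeightedMedianEstimator",
    "ModeEstimator",
    "MedianMVMREstimator",
    "DegenerateDesignError",
    "ConvergenceError",
    "weighted_median",
]

Z_95 = 1.959963984540054  # normal 97.5% quantile


class DegenerateDesignError(ValueError):
    """Design matrix is rank deficient (collinear or constant exposures)."""


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_coef: np.ndarray):
        super().__init__(message)
        self.last_coef = last_coef


def _as_design(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _check_rank(X: np.ndarray, names=None) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        cols = names if names is not None else list(range(X.shape[1]))
        raise DegenerateDesignError(
            f"design matrix is rank deficient; check exposure columns {cols}"
        )


class _WLSMixin:
    """Shared post-fit bookkeeping: CIs, p-values, odds ratios."""

    def _finalize(self, coef, se, k):
        self.coef_ = np.asarray(coef, dtype=float)
        self.se_ = np.asarray(se, dtype=float)
        self.n_snv_ = int(k)
        self.ci_low_ = self.coef_ - Z_95 * self.se_
        self.ci_high_ = self.coef_ + Z_95 * self.se_
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se_ > 0, self.coef_ / self.se_, np.inf * np.sign(self.coef_))
        z = np.where(self.coef_ == 0, 0.0, z)
        self.pvalue_ = np.clip(2.0 * stats.norm.sf(np.abs(z)), 5e-324, 1.0)
        return self


class IVWEstimator(_WLSMixin, BaseEstimator):
    """Inverse-variance-weighted estimator (uni- or multivariable).

    Weighted zero-intercept regression of outcome effects on exposure
    effects with weights ``1/se_y**2``.  With one exposure column this is
    algebraically identical to the weighted mean of per-variant Wald ratios
    ``r_j = beta_y / beta_x`` with weights ``beta_x**2 / se_y**2``.

    Parameters
    ----------
    model : {"random", "fixed"}
        ``random`` applies multiplicative over-dispersion scaling
        ``max(1, sqrt(Q/(k - m)))`` to the fixed-effects standard errors.

    Attributes
    ----------
    coef_, se_, ci_low_, ci_high_, pvalue_ : ndarray of shape (m,)
    q_, q_df_, q_pvalue_ : float — Cochran's Q heterogeneity test
    dispersion_ : float — the applied over-dispersion factor (>= 1)
    """

    def __init__(self, model: str = "random"):
        self.model = model

    def fit(self, X, y, se_y=None, exposure_names=None):
        if se_y is None:
            raise ValueError("se_y (outcome standard errors) is required")
        X = _as_design(X)
        y = np.asarray(y, dtype=float).ravel()
        se_y = np.asarray(se_y, dtype=float).ravel()
        k, m = X.shape
        if k < m:
            raise ValueError(f"need at least {m} variants for {m} exposures, got {k}")
        if not np.any(X):
            raise DegenerateDesignError("all exposure effects are zero")
        _check_rank(X, exposure_names)
        w = 1.0 / se_y**2
        res = sm.WLS(y, X, weights=w).fit()
        resid = y - X @ res.params
        self.q_ = float(np.sum(w * resid**2))
        self.q_df_ = max(k - m, 0)
        self.q_pvalue_ = (
            float(stats.chi2.sf(self.q_, self.q_df_)) if self.q_df_ > 0 else float("nan")
        )
        cov_fixed = np.linalg.inv(X.T @ (w[:, None] * X))
        se_fixed = np.sqrt(np.diag(cov_fixed))
        if self.model == "random" and self.q_df_ > 0:
            self.dispersion_ = max(1.0, np.sqrt(self.q_ / self.q_df_))
        else:
            self.dispersion_ = 1.0
        return self._finalize(res.params, se_fixed * self.dispersion_, k)

    def predict(self, X):
        return _as_design(X) @ self.coef_


class EggerEstimator(_WLSMixin, BaseEstimator):
    """MR-Egger regression (uni- or multivariable).

    As :class:`IVWEstimator` but with an intercept, whose deviation from
    zero estimates directional horizontal pleiotropy.  Variants are first
    oriented so the first exposure's effects are non-negative (outcome and
    remaining exposure effects flip sign with them); the orientation is
    re-derived internally, so callers need not canonicalize.

    Additional attributes: ``intercept_``, ``intercept_se_``,
    ``intercept_ci_low_``, ``intercept_ci_high_``, ``intercept_pvalue_``.
    """

    def __init__(self, model: str = "random"):
        self.model = model

    def fit(self, X, y, se_y=None, exposure_names=None):
        if se_y is None:
            raise ValueError("se_y (outcome standard errors) is required")
        X = _as_design(X)
        y = np.asarray(y, dtype=float).ravel()
        se_y = np.asarray(se_y, dtype=float).ravel()
        k, m = X.shape
        if k < m + 2:
            raise ValueError(f"MR-Egger needs at least {m + 2} variants, got {k}")
        flip = np.where(X[:, 0] < 0, -1.0, 1.0)
        Xo = X * flip[:, None]
        yo = y * flip
        if np.ptp(Xo[:, 0]) == 0:
            raise DegenerateDesignError(
                "no spread in |exposure effects|; intercept and slope are collinear"
            )
        design = sm.add_constant(Xo)
        _check_rank(design, exposure_names)
        w = 1.0 / se_y**2
        res = sm.WLS(yo, design, weights=w).fit()
        resid = yo - design @ res.params
        self.q_ = float(np.sum(w * resid**2))
        self.q_df_ = max(k - m - 1, 0)
        self.q_pvalue_ = (
            float(stats.chi2.sf(self.q_, self.q_df_)) if self.q_df_ > 0 else float("nan")
        )
        cov_fixed = np.linalg.inv(design.T @ (w[:, None] * design))
        se_fixed = np.sqrt(np.diag(cov_fixed))
        if self.model == "random" and self.q_df_ > 0:
            self.dispersion_ = max(1.0, np.sqrt(self.q_ / self.q_df_))
        else:
            self.dispersion_ = 1.0
        se_all = se_fixed * self.dispersion_
        self.intercept_ = float(res.params[0])
        self.intercept_se_ = float(se_all[0])
        self.intercept_ci_low_ = self.intercept_ - Z_95 * self.intercept_se_
        self.intercept_ci_high_ = self.intercept_ + Z_95 * self.intercept_se_
        self.intercept_pvalue_ = float(
            np.clip(2.0 * stats.norm.sf(abs(self.intercept_ / self.intercept_se_)), 5e-324, 1.0)
        )
        return self._finalize(res.params[1:], se_all[1:], k)

    def predict(self, X):
        X = _as_design(X)
        return self.intercept_ + X @ self.coef_


def weighted_median(values, weights) -> float:
    """Weighted median by the cumulative-weight interpolation rule.

    Sort ``values``; with weights normalized to sum one, the cumulative
    weight of the j-th order statistic is ``s_j = sum_{i<=j} w_i - w_j/2``;
    the estimate linearly interpolates values at ``s = 1/2``.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, v))


class WeightedMedianEstimator(_WLSMixin, BaseEstimator):
    """Weighted median of Wald ratios (univariable only).

    Consistent when variants carrying at least half of the weight are valid
    instruments.  Ratio weights are ``beta_x**2 / se_y**2``; the standard
    error comes from a parametric bootstrap that redraws per-variant betas
    from normal distributions with their reported standard errors.

    Parameters
    ----------
    n_boot : int
        Bootstrap replicates for the standard error.
    random_state : int or numpy Generator
        Seeds the bootstrap; required for reproducible intervals.
    """

    def __init__(self, n_boot: int = 1000, random_state=None):
        self.n_boot = n_boot
        self.random_state = random_state

    @staticmethod
    def _point(beta_x, beta_y, se_y):
        ratios = beta_y / beta_x
        w = beta_x**2 / se_y**2
        return weighted_median(ratios, w)

    def fit(self, X, y, se_y=None, se_x=None):
        if se_y is None:
            raise ValueError("se_y (outcome standard errors) is required")
        X = _as_design(X)
        if X.shape[1] != 1:
            raise ValueError("the weighted median estimator is univariable")
        beta_x = X[:, 0]
        beta_y = np.asarray(y, dtype=float).ravel()
        se_y = np.asarray(se_y, dtype=float).ravel()
        k = beta_x.size
        if k < 3:
            raise ValueError(f"weighted median needs at least 3 variants, got {k}")
        est = self._point(beta_x, beta_y, se_y)
        se = _parametric_bootstrap_se(
            self._point, beta_x, beta_y, se_y, se_x, self.n_boot, self.random_state
        )
        return self._finalize([est], [se], k)


class ModeEstimator(_WLSMixin, BaseEstimator):
    """Mode-based estimate: the densest cluster of Wald ratios.

    A normal-kernel density is fitted to the per-variant ratios (weighted by
    inverse ratio variance for ``kind="weighted"``, equally for
    ``kind="simple"``) and the estimate is its argmax on a 512-point grid
    spanning the ratios plus three bandwidths.  Bandwidth follows the
    normal-reference rule ``phi * 0.9 * min(sd, iqr/1.349) * k**(-1/5)``.
    Ties between equally-dense modes break toward the smaller value with a
    warning.  Standard errors are parametric-bootstrap, as in
    :class:`WeightedMedianEstimator`.
    """

    GRID_POINTS = 512

    def __init__(self, kind: str = "weighted", phi: float = 1.0, n_boot: int = 1000,
                 random_state=None):
        self.kind = kind
        self.phi = phi
        self.n_boot = n_boot
        self.random_state = random_state

    def _point(self, beta_x, beta_y, se_y, warn: bool = False):
        ratios = beta_y / beta_x
        if self.kind == "weighted":
            w = beta_x**2 / se_y**2
        else:
            w = np.ones_like(ratios)
        w = w / w.sum()
        if np.ptp(ratios) == 0:
            return float(ratios[0])
        sd = float(np.std(ratios, ddof=1))
        iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
        candidates = [c for c in (sd, iqr / 1.349) if c > 0]
        h = self.phi * 0.9 * min(candidates) * ratios.size ** (-0.2)
        if h <= 0:
            raise ValueError("zero kernel bandwidth; increase phi or check input spread")
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, self.GRID_POINTS)
        dens = np.sum(
            w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2), axis=0
        )
        peak = dens.max()
        at_peak = np.flatnonzero(np.isclose(dens, peak, rtol=0.0, atol=peak * 1e-12))
        if warn and at_peak.size > 1 and np.ptp(grid[at_peak]) > 2 * (grid[1] - grid[0]):
            warnings.warn(
                "multiple equally dense modes; breaking the tie toward the smaller",
                stacklevel=2,
            )
        return float(grid[at_peak[0]])

    def fit(self, X, y, se_y=None, se_x=None):
        if se_y is None:
            raise ValueError("se_y (outcome standard errors) is required")
        if self.phi <= 0:
            raise ValueError("bandwidth factor phi must be positive")
        X = _as_design(X)
        if X.shape[1] != 1:
            raise ValueError("mode-based estimators are univariable")
        beta_x = X[:, 0]
        beta_y = np.asarray(y, dtype=float).ravel()
        se_y = np.asarray(se_y, dtype=float).ravel()
        k = beta_x.size
        if k < 3:
            raise ValueError(f"mode estimators need at least 3 variants, got {k}")
        est = self._point(beta_x, beta_y, se_y, warn=True)
        se = _parametric_bootstrap_se(
            self._point, beta_x, beta_y, se_y, se_x, self.n_boot, self.random_state
        )
        return self._finalize([est], [se], k)


class MedianMVMREstimator(_WLSMixin, BaseEstimator):
    """Multivariable median regression of outcome on exposure effects.

    Solves the weighted least-absolute-deviation fit of ``beta_y`` on the
    exposure-effect matrix (weights ``1/se_y**2``, no intercept) by
    iteratively reweighted least squares with smoothing constant ``eps`` in
    the weight denominators.  Standard errors by parametric bootstrap.
    """

    def __init__(self, n_boot: int = 200, random_state=None, tol: float = 1e-8,
                 max_iter: int = 1000, eps: float = 1e-6):
        self.n_boot = n_boot
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter
        self.eps = eps

    def _point(self, X, y, se_y):
        X = _as_design(X)
        w = 1.0 / np.asarray(se_y, float) ** 2
        coef = np.linalg.lstsq(np.sqrt(w)[:, None] * X, np.sqrt(w) * y, rcond=None)[0]
        best, best_obj, stall = coef, np.inf, 0
        for _ in range(self.max_iter):
            resid = y - X @ coef
            wi = w / np.maximum(np.abs(resid), self.eps)
            new = np.linalg.lstsq(np.sqrt(wi)[:, None] * X, np.sqrt(wi) * y, rcond=None)[0]
            if np.max(np.abs(new - coef)) < self.tol:
                return new
            # near the smoothing kink IRLS can cycle without the coefficients
            # settling; track the best weighted-L1 objective and stop once it
            # stops improving
            obj = float(np.sum(w * np.abs(y - X @ new)))
            improving = obj < best_obj - 1e-8 * max(
                best_obj if np.isfinite(best_obj) else 0.0, 1e-300
            )
            if improving:
                best, best_obj, stall = new, obj, 0
            else:
                stall += 1
                if stall >= 10:
                    return best
            coef = new
        raise ConvergenceError(
            f"IRLS median regression did not converge in {self.max_iter} iterations",
            best,
        )

    def fit(self, X, y, se_y=None, se_x=None, exposure_names=None):
        if se_y is None:
            raise ValueError("se_y (outcome standard errors) is required")
        X = _as_design(X)
        y = np.asarray(y, dtype=float).ravel()
        se_y = np.asarray(se_y, dtype=float).ravel()
        k, m = X.shape
        if k < m + 1:
            raise ValueError(f"need more variants ({k}) than exposures ({m})")
        _check_rank(X, exposure_names)
        coef = self._point(X, y, se_y)
        rng = _rng(self.random_state)
        boots = np.empty((self.n_boot, m))
        for b in range(self.n_boot):
            Xb = X if se_x is None else rng.normal(X, np.broadcast_to(se_x, X.shape))
            yb = rng.normal(y, se_y)
            try:
                boots[b] = self._point(Xb, yb, se_y)
            except ConvergenceError as exc:  # rare; keep the last iterate
                boots[b] = exc.last_coef
        se = boots.std(axis=0, ddof=1)
        return self._finalize(coef, se, k)

    def predict(self, X):
        return _as_design(X) @ self.coef_


def _rng(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


def _parametric_bootstrap_se(point_fn, beta_x, beta_y, se_y, se_x, n_boot, random_state):
    """SD of the point estimate over parametric redraws of the betas."""
    rng = _rng(random_state)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx = beta_x if se_x is None else rng.normal(beta_x, se_x)
        by = rng.normal(beta_y, se_y)
        est[b] = point_fn(bx, by, se_y)
    return float(est.std(ddof=1))
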