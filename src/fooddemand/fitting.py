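"""Regression machinery: saturating-curve and power-law estimators, goodness
of fit, and k-fold country cross-validation.

The two estimators follow the scikit-learn contract (``fit`` / ``predict`` /
``get_params`` / fitted attributes with trailing underscores) so they compose
with sklearn pipelines and model selection.  The saturating fit uses
:func:`scipy.optimize.least_squares` with a seeded, deterministic multi-start
over the half-saturation constant (0.1x, 1x, 10x the median driver value);
the best residual sum of squares wins, ties broken by the smallest
half-saturation.  Drivers are internally rescaled by their median, which
makes the fit exactly scale-equivariant: rescaling x by m rescales the
half-saturation estimate by m and leaves the asymptote unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .parameters import PowerLaw, SaturatingCurve

__all__ = [
    "FitResult", "CVReport", "SaturatingRegressor", "PowerLawRegressor",
    "fit_saturating", "fit_power_law", "r_squared", "kfold_cv",
]


@dataclass
class FitResult:
    """Parameter estimates with standard errors and fit diagnostics."""

    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    r2: float
    converged: bool
    n_obs: int
    message: str = ""

    def to_dict(self) -> dict:
        return {"params": self.params, "stderr": self.stderr, "rss": self.rss,
                "r2": self.r2, "converged": self.converged,
                "n_obs": self.n_obs, "message": self.message}


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - RSS/TSS``.

    Negative when the predictor is worse than the observed mean; raises on
    constant observations (TSS = 0).
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("observed values are constant; R^2 undefined")
    rss = float(np.sum((obs - pred) ** 2))
    return 1.0 - rss / tss


def _column(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("X must be 1-d or a single-column 2-d array")
    return x


class SaturatingRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least squares for ``y = offset + c + a*x/(b + x)``.

    Parameters
    ----------
    fit_baseline : bool
        Whether the additive baseline ``c`` is estimated (population-share
        curves) or fixed at 0 (waste ratio, diet-tree shares).
    offset : float
        Fixed additive offset (1.0 for the demand/intake ratio).
    asymptote_bounds, baseline_bounds : tuple
        Box constraints on ``a`` and ``c``; the asymptote may be negative for
        shares that shrink with the driver.
    halfsat_starts : tuple
        Multi-start factors applied to the median of x.
    tol : float
        ``xtol``/``ftol``/``gtol`` passed to the optimizer; tight by default
        so noiseless synthetic data are recovered to near machine precision.
    """

    def __init__(self, fit_baseline=True, offset=0.0,
                 asymptote_bounds=(-1.0, 1.0), baseline_bounds=(0.0, 1.0),
                 halfsat_starts=(0.1, 1.0, 10.0), tol=1e-13):
        self.fit_baseline = fit_baseline
        self.offset = offset
        self.asymptote_bounds = asymptote_bounds
        self.baseline_bounds = baseline_bounds
        self.halfsat_starts = halfsat_starts
        self.tol = tol

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y):
        x = _column(X)
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        if np.any(x < 0):
            raise ValueError("driver values must be non-negative")
        if np.unique(x).size < 3:
            raise ValueError("need at least 3 distinct driver values")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in fitting data")

        scale = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
        u = x / scale
        yy = y - self.offset
        self.n_obs_ = x.size
        self.identifiable_ = True

        if np.ptp(yy) == 0.0:
            # flat response: asymptote 0, half-saturation unidentifiable
            const = float(yy[0])
            self.baseline_ = const if self.fit_baseline else 0.0
            self.asymptote_ = 0.0 if self.fit_baseline else const
            self.half_saturation_ = scale
            self.identifiable_ = False
            self.converged_ = True
            self.stderr_ = {}
            self._finalize(x, y)
            return self

        a_lo, a_hi = self.asymptote_bounds
        if self.fit_baseline:
            c_lo, c_hi = self.baseline_bounds
            c0 = float(np.clip(yy[np.argmin(u)], c_lo, c_hi))
            lo, hi = [a_lo, 1e-6, c_lo], [a_hi, 1e6, c_hi]

            def resid(p):
                a, b, c = p
                return c + a * u / (b + u) - yy
        else:
            c0 = 0.0
            lo, hi = [a_lo, 1e-6], [a_hi, 1e6]

            def resid(p):
                a, b = p
                return a * u / (b + u) - yy

        a0 = float(np.clip(yy[np.argmax(u)] - c0, a_lo + 1e-9, a_hi - 1e-9))
        if a0 == 0.0:
            a0 = 0.5 * (a_lo + a_hi) or 0.1

        best = None
        for b0 in self.halfsat_starts:
            p0 = [a0, b0, c0] if self.fit_baseline else [a0, b0]
            try:
                res = least_squares(resid, p0, bounds=(lo, hi), xtol=self.tol,
                                    ftol=self.tol, gtol=self.tol,
                                    max_nfev=2000)
            except Exception:  # pragma: no cover - optimizer blow-up
                continue
            if not res.success:
                continue
            rss = float(2 * res.cost)
            if (best is None or rss < best[0] - 1e-15 * (1 + best[0])
                    or (abs(rss - best[0]) <= 1e-15 * (1 + best[0])
                        and res.x[1] < best[1].x[1])):
                best = (rss, res)
        if best is None:
            raise RuntimeError(
                "saturating fit failed to converge from all starts "
                f"(n={x.size}, starts={self.halfsat_starts})")

        rss, res = best
        self.asymptote_ = float(res.x[0])
        self.half_saturation_ = float(res.x[1] * scale)
        self.baseline_ = float(res.x[2]) if self.fit_baseline else 0.0
        self.converged_ = True
        self.stderr_ = self._standard_errors(res, scale, x.size)
        self._finalize(x, y)
        return self

    def _standard_errors(self, res, scale, n) -> dict[str, float]:
        p = res.x.size
        if n <= p:
            return {}
        sigma2 = 2 * res.cost / (n - p)
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * sigma2
        except np.linalg.LinAlgError:
            return {}
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        out = {"asymptote": float(se[0]), "half_saturation": float(se[1] * scale)}
        if self.fit_baseline:
            out["baseline"] = float(se[2])
        return out

    def _finalize(self, x, y):
        pred = self.predict(x)
        self.rss_ = float(np.sum((y - pred) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - self.rss_ / tss if tss > 0 else float("nan")

    # -- inference -----------------------------------------------------------

    def predict(self, X):
        x = _column(X)
        return (self.offset + self.baseline_
                + self.asymptote_ * x / (self.half_saturation_ + x))

    def curve_(self) -> SaturatingCurve:
        return SaturatingCurve(self.baseline_, self.asymptote_,
                               self.half_saturation_)

    @property
    def fit_result_(self) -> FitResult:
        params = {"asymptote": self.asymptote_,
                  "half_saturation": self.half_saturation_}
        if self.fit_baseline:
            params["baseline"] = self.baseline_
        msg = "" if self.identifiable_ else "flat response; half-saturation unidentifiable"
        return FitResult(params=params, stderr=self.stderr_, rss=self.rss_,
                         r2=self.r2_, converged=self.converged_,
                         n_obs=self.n_obs_, message=msg)


class PowerLawRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares for ``y = alpha * x**beta`` in log-log space.

    The fit is the closed-form OLS of ``log y`` on ``log x``; ``alpha`` is
    back-transformed from the intercept.  Non-positive values are an error
    (the logarithm is undefined), and a single distinct x value is a
    rank-deficient design.
    """

    def fit(self, X, y):
        x = _column(X)
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("power-law fit requires strictly positive x and y")
        if np.unique(x).size < 2:
            raise ValueError("degenerate design: a single distinct x value")
        lx, ly = np.log(x), np.log(y)
        A = np.column_stack([np.ones_like(lx), lx])
        coef, _, _, _ = np.linalg.lstsq(A, ly, rcond=None)
        self.alpha_ = float(np.exp(coef[0]))
        self.beta_ = float(coef[1])
        self.n_obs_ = x.size
        resid = ly - A @ coef
        self.rss_ = float(resid @ resid)
        tss = float(np.sum((ly - ly.mean()) ** 2))
        self.r2_ = 1.0 - self.rss_ / tss if tss > 0 else float("nan")
        self.converged_ = True
        # OLS standard errors in log space
        if x.size > 2:
            sigma2 = self.rss_ / (x.size - 2)
            cov = sigma2 * np.linalg.inv(A.T @ A)
            self.stderr_ = {"log_alpha": float(np.sqrt(cov[0, 0])),
                            "beta": float(np.sqrt(cov[1, 1]))}
        else:
            self.stderr_ = {}
        return self

    def predict(self, X):
        x = _column(X)
        return self.alpha_ * np.power(x, self.beta_)

    def curve_(self) -> PowerLaw:
        return PowerLaw(self.alpha_, self.beta_)

    @property
    def fit_result_(self) -> FitResult:
        return FitResult(params={"alpha": self.alpha_, "beta": self.beta_},
                         stderr=self.stderr_, rss=self.rss_, r2=self.r2_,
                         converged=True, n_obs=self.n_obs_,
                         message="R^2 and RSS are in log space")


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_saturating(x, y, fit_baseline=True, offset=0.0,
                   asymptote_bounds=(-1.0, 1.0),
                   baseline_bounds=(0.0, 1.0)) -> FitResult:
    est = SaturatingRegressor(fit_baseline=fit_baseline, offset=offset,
                              asymptote_bounds=asymptote_bounds,
                              baseline_bounds=baseline_bounds).fit(x, y)
    return est.fit_result_


def fit_power_law(x, y) -> FitResult:
    return PowerLawRegressor().fit(x, y).fit_result_


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVReport:
    """Out-of-sample R^2 per indicator, per fold and pooled.

    Folds partition the country set (never years); fold sizes differ by at
    most one.
    """

    fold_assignment: dict[str, int]
    per_fold: list[dict[str, float]]
    pooled: dict[str, float]

    @property
    def k(self) -> int:
        return len(self.per_fold)

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, scores in enumerate(self.per_fold):
            for ind, r2 in scores.items():
                rows.append({"fold": i, "indicator": ind, "r2": r2})
        for ind, r2 in self.pooled.items():
            rows.append({"fold": "pooled", "indicator": ind, "r2": r2})
        return pd.DataFrame(rows)


def kfold_cv(countries, k: int, seed: int, fit_and_predict) -> CVReport:
    """K-fold cross-validation over countries.

    ``fit_and_predict(train_countries, test_countries)`` must fit on the
    training countries and return ``{indicator: (observed, predicted)}``
    arrays for the held-out countries.  The country partition is determined
    entirely by ``seed``.
    """
    countries = [str(c) for c in countries]
    if k > len(countries):
        raise ValueError(f"k={k} exceeds the number of countries "
                         f"({len(countries)})")
    splitter = KFold(n_splits=k, shuffle=True, random_state=int(seed))
    arr = np.array(sorted(countries))
    fold_assignment: dict[str, int] = {}
    per_fold: list[dict[str, float]] = []
    pools: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for fold, (train_idx, test_idx) in enumerate(splitter.split(arr)):
        train, test = list(arr[train_idx]), list(arr[test_idx])
        for c in test:
            fold_assignment[c] = fold
        scores = {}
        for indicator, (obs, pred) in fit_and_predict(train, test).items():
            obs = np.asarray(obs, dtype=float).ravel()
            pred = np.asarray(pred, dtype=float).ravel()
            keep = np.isfinite(obs) & np.isfinite(pred)
            obs, pred = obs[keep], pred[keep]
            pools.setdefault(indicator, []).append((obs, pred))
            if obs.size >= 2 and np.ptp(obs) > 0:
                scores[indicator] = r_squared(obs, pred)
            else:
                scores[indicator] = float("nan")
        per_fold.append(scores)
    pooled = {}
    for indicator, chunks in pools.items():
        obs = np.concatenate([o for o, _ in chunks])
        pred = np.concatenate([p for _, p in chunks])
        pooled[indicator] = r_squared(obs, pred)
    return CVReport(fold_assignment=fold_assignment, per_fold=per_fold,
                    pooled=pooled)
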