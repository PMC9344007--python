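"""Quantitation layer: PLS/MLR regression, cross-validated error, the
peak-height calibration curve, detection limit and reproducibility
statistics, and characteristic-peak detection.

PLS is NIPALS PLS1 (single response): X and y are column-centered, then
latent variables are extracted one at a time — the weight vector is the
covariance direction X^T y (normalised), scores t = X w, loadings
p = X^T t / (t^T t), response loading q = y^T t / (t^T t), and X and y are
deflated before the next component.  The regression coefficient vector is
assembled as B = W (P^T W)^{-1} q.  With as many latent variables as the
rank of X, PLS1 predictions coincide with ordinary least squares.

RMSECV is the root-mean-square error of cross-validated predictions with
deterministic fold assignment (contiguous blocks after sorting by y);
leave-one-out is the default at typical sample counts (tens).

LOD follows the blank-based rule: the concentration whose calibration
response equals mean(blank) + 3 * SD(blank) — or 3 * mean(blank) under the
``3s_only`` rule — floored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .io import Spectrum

__all__ = [
    "RegressionModel",
    "CalibrationCurve",
    "Metrics",
    "pls_fit",
    "mlr_fit",
    "rmsecv",
    "fit_calibration",
    "lod",
    "rsd",
    "detect_peaks",
]


@dataclass
class RegressionModel:
    """Linear map from a feature vector to predicted concentration."""

    method: str
    coefficients: np.ndarray  # (d,)
    x_mean: np.ndarray
    y_mean: float
    n_latent: int | None = None

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coefficients + self.y_mean


@dataclass
class CalibrationCurve:
    """Peak-intensity-vs-concentration line I = slope * N + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")


@dataclass
class Metrics:
    """Headline quantitation statistics (all non-negative)."""

    rmsecv: float
    rsd_percent: float
    lod: float

    def __post_init__(self):
        for name in ("rmsecv", "rsd_percent", "lod"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def pls_fit(X, y, n_latent: int) -> RegressionModel:
    """NIPALS PLS1 regression of a single response on a feature matrix.

    ``n_latent`` must not exceed min(rank(centered X), n_samples - 1).
    A constant response yields zero coefficients (predictions = mean(y)).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on sample count")
    if n_latent < 1:
        raise ValueError("n_latent must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    X0 = X - x_mean
    rank = np.linalg.matrix_rank(X0)
    bound = min(rank, n - 1)
    if n_latent > bound:
        raise ValueError(
            f"n_latent={n_latent} exceeds min(rank(X)={rank}, n-1={n - 1}) = {bound}"
        )

    Xk = X0.copy()
    yk = y - y_mean
    scale = max(float(np.abs(X0).max()), 1.0) * max(float(np.abs(yk).max()), 1.0)
    W, P, Q = [], [], []
    for _ in range(n_latent):
        w = Xk.T @ yk
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * scale:
            break  # no covariance left to extract (e.g. constant y)
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        if tt <= 1e-30:
            break
        p = Xk.T @ t / tt
        q = float(yk @ t) / tt
        Xk = Xk - np.outer(t, p)
        yk = yk - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    if not W:
        return RegressionModel("pls", np.zeros(d), x_mean, y_mean, n_latent=0)
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.array(Q)
    coef = Wm @ np.linalg.solve(Pm.T @ Wm, qv)
    return RegressionModel("pls", coef, x_mean, y_mean, n_latent=len(W))


def mlr_fit(X, y) -> RegressionModel:
    """Ordinary least squares with intercept (multiple linear regression)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on sample count")
    if n <= d:
        raise ValueError(
            f"MLR needs more samples ({n}) than features ({d}); "
            "reduce dimensionality with KPCA or use PLS"
        )
    X0 = X - X.mean(axis=0)
    if np.linalg.matrix_rank(X0) < d:
        raise ValueError(
            "feature matrix is rank-deficient; reduce dimensionality with KPCA or use PLS"
        )
    coef, *_ = np.linalg.lstsq(X0, y - y.mean(), rcond=None)
    return RegressionModel("mlr", coef, X.mean(axis=0), float(y.mean()))


def _resolve_model(model_spec):
    """Accept a factory callable or a {'method': ...} dict."""
    if callable(model_spec):
        return model_spec
    spec = dict(model_spec)
    method = spec.pop("method")
    if method == "pls":
        n_latent = spec.pop("n_latent", 2)

        def factory(X_tr, y_tr):
            bound = min(
                np.linalg.matrix_rank(X_tr - np.mean(X_tr, axis=0)), len(y_tr) - 1
            )
            model = pls_fit(X_tr, y_tr, max(1, min(n_latent, bound)))
            return model.predict

    elif method == "mlr":

        def factory(X_tr, y_tr):
            return mlr_fit(X_tr, y_tr).predict

    elif method == "mean":

        def factory(X_tr, y_tr):
            m = float(np.mean(y_tr))
            return lambda X_te: np.full(np.atleast_2d(X_te).shape[0], m)

    else:
        raise ValueError(f"unknown regression method {method!r}")
    return factory


def rmsecv(X, y, model_spec, folds: int | None = None) -> float:
    """Root-mean-square error of cross-validated predictions.

    ``model_spec`` is a factory ``fit(X_train, y_train) -> predict`` or a
    dict like ``{'method': 'pls', 'n_latent': 3}``.  ``folds=None`` means
    leave-one-out; otherwise folds are contiguous blocks after sorting by
    y, so the assignment is deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if folds is None:
        folds = n
    if not 2 <= folds <= n:
        raise ValueError(f"folds must lie in [2, {n}], got {folds}")
    factory = _resolve_model(model_spec)
    order = np.argsort(y, kind="stable")
    blocks = np.array_split(order, folds)
    preds = np.empty(n)
    for block in blocks:
        train = np.setdiff1d(np.arange(n), block)
        predict = factory(X[train], y[train])
        preds[block] = np.asarray(predict(X[block]), dtype=float).ravel()
    return float(np.sqrt(np.mean((preds - y) ** 2)))


def fit_calibration(intensities, concentrations) -> CalibrationCurve:
    """OLS line I = slope * N + intercept with r^2 = squared Pearson r."""
    I = np.asarray(intensities, dtype=float).ravel()
    N = np.asarray(concentrations, dtype=float).ravel()
    if I.shape != N.shape or I.shape[0] < 2:
        raise ValueError("calibration needs >= 2 paired (intensity, concentration) points")
    if np.unique(N).size < 2:
        raise ValueError("calibration needs at least 2 distinct concentrations")
    res = _stats.linregress(N, I)
    r2 = float(res.rvalue**2)
    if I.shape[0] == 2:
        r2 = 1.0  # two distinct points define an exact line
    return CalibrationCurve(float(res.slope), float(res.intercept), min(r2, 1.0))


def lod(blank_intensities, curve: CalibrationCurve, rule: str = "mean_plus_3sd") -> float:
    """Limit of detection from replicate blank signals and the calibration.

    ``mean_plus_3sd``: concentration at mean(blank) + 3 * SD(blank);
    ``3s_only``: concentration at 3 * mean(blank).  Sample SD (ddof=1).
    Result floored at 0.
    """
    blanks = np.asarray(blank_intensities, dtype=float).ravel()
    if blanks.shape[0] < 3:
        raise ValueError("LOD needs at least 3 blank replicates")
    if curve.slope <= 0:
        raise ValueError(f"calibration slope must be > 0, got {curve.slope}")
    if rule == "mean_plus_3sd":
        critical = float(blanks.mean() + 3.0 * blanks.std(ddof=1))
    elif rule == "3s_only":
        critical = float(3.0 * blanks.mean())
    else:
        raise ValueError(f"unknown LOD rule {rule!r}")
    return max(0.0, (critical - curve.intercept) / curve.slope)


def rsd(values) -> float:
    """Relative standard deviation, 100 * sample SD / mean, in percent."""
    v = np.asarray(values, dtype=float).ravel()
    if v.shape[0] < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = float(v.mean())
    if mean == 0:
        raise ValueError("RSD is undefined for zero mean")
    return 100.0 * float(v.std(ddof=1)) / mean


def detect_peaks(
    spectrum: Spectrum,
    min_prominence: float = 0.05,
    min_separation: float = 20.0,
) -> list[tuple[float, float]]:
    """Locate characteristic peaks as (center, height) pairs.

    ``min_prominence`` is a fraction of the spectrum's intensity range
    (max - min), which makes detection invariant to constant offsets;
    ``min_separation`` is the minimum center spacing in cm^-1.  Centers and
    heights are refined by 3-point parabolic interpolation; output sorted
    by wavenumber.
    """
    nu = spectrum.wavenumbers
    y = spectrum.intensities
    span = float(y.max() - y.min())
    if span <= 0:
        return []
    step = float(np.mean(np.diff(nu)))
    distance = max(1, int(np.ceil(min_separation / step)))
    idx, _ = _signal.find_peaks(y, prominence=min_prominence * span, distance=distance)
    out = []
    for i in idx:
        if 0 < i < len(y) - 1:
            ym, y0, yp = y[i - 1], y[i], y[i + 1]
            denom = ym - 2.0 * y0 + yp
            delta = 0.5 * (ym - yp) / denom if denom != 0 else 0.0
            center = nu[i] + delta * step
            height = y0 - 0.25 * (ym - yp) * delta
        else:
            center, height = float(nu[i]), float(y[i])
        out.append((float(center), float(height)))
    return sorted(out)
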