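"""Kernel principal component analysis with an RBF kernel.

Samples x_mu are implicitly mapped to a feature space via the kernel
k(x, y) = exp(-||x - y||^2 / (2 sigma^2)).  PCA is performed on the Gram
matrix K, K_{mu nu} = k(x_mu, x_nu), after the double-centering correction

    K_{mu nu} -> K_{mu nu} - (1/M)(sum_w K_{mu w} + sum_w K_{w nu})
                 + (1/M^2) sum_{w,tau} K_{w tau}

which enforces zero-mean mapped features; the correction equals H K H with
H = I - (1/M) 11^T.  A component's coefficient vector alpha_k (the
eigenvector of the centered Gram matrix) is scaled so that
lambda_k (alpha_k . alpha_k) = 1, making the feature-space eigenvector
unit-norm, and the projection of a point x onto component k is

    score_k(x) = sum_i alpha_i^k k(x_i, x)

with the test kernel row centered against the training statistics.  A
``kernel='linear'`` variant (k(x,y) = x.y) exists for the classical-PCA
comparison: its scores equal covariance-PCA scores up to per-component
sign.

sigma is expressed in the same units as feature-space Euclidean distances,
i.e. raw intensity counts for unnormalised spectra — the natural scale of
the sweep grid {1000, 5000, 8000, 10000}.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "KPCAModel",
    "ScoreTable",
    "rbf_kernel",
    "kernel_matrix",
    "center_kernel",
    "kpca_fit",
    "kpca_transform",
    "sigma_sweep",
    "DEFAULT_SIGMA_GRID",
]

DEFAULT_SIGMA_GRID = (1000.0, 5000.0, 8000.0, 10000.0)
_EIG_TOL = 1e-12


def rbf_kernel(x, y, sigma: float) -> float:
    """exp(-||x - y||^2 / (2 sigma^2)) for two feature vectors."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    d2 = float(((x - y) ** 2).sum())
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def kernel_matrix(X, Y, sigma: float | None, kernel: str = "rbf") -> np.ndarray:
    """Pairwise kernel evaluations, rows of X against rows of Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"feature count mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if kernel == "rbf":
        if sigma is None or sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {sigma}")
        return np.exp(-cdist(X, Y, "sqeuclidean") / (2.0 * sigma**2))
    if kernel == "linear":
        return X @ Y.T
    raise ValueError(f"unknown kernel {kernel!r}")


def center_kernel(K: np.ndarray) -> np.ndarray:
    """Double-centering correction of a square kernel matrix.

    Implements the elementwise correction (row sums + column sums removed,
    grand mean restored); for symmetric K this equals H K H.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"kernel matrix must be square, got shape {K.shape}")
    M = K.shape[0]
    row = K.sum(axis=1, keepdims=True)
    col = K.sum(axis=0, keepdims=True)
    total = K.sum()
    return K - (row + col) / M + total / M**2


@dataclass
class KPCAModel:
    """Fitted kernel PCA model (training data, kernel and eigensystem)."""

    training_features: np.ndarray
    sigma: float | None
    kernel: str
    kernel_matrix: np.ndarray
    centered_kernel: np.ndarray
    eigenvalues: np.ndarray  # all eigenvalues, descending
    coefficients: np.ndarray  # (M, n_components), alpha_k columns
    n_components: int

    @property
    def training_scores(self) -> np.ndarray:
        return self.centered_kernel @ self.coefficients

    @property
    def explained_ratio(self) -> np.ndarray:
        """Retained eigenvalue mass over total non-negative eigenvalue mass."""
        pos = self.eigenvalues[self.eigenvalues > 0]
        denom = pos.sum() if pos.size else 1.0
        return np.clip(self.eigenvalues[: self.n_components], 0.0, None) / denom


@dataclass
class ScoreTable:
    """Projections (samples x components) with per-component variance share."""

    scores: np.ndarray
    explained_ratio: np.ndarray
    sample_ids: list[str] | None = None


def kpca_fit(
    X, sigma: float | None = None, n_components: int | None = None, kernel: str = "rbf"
) -> KPCAModel:
    """Fit kernel PCA on an (M, d) training matrix.

    Components whose eigenvalue is <= 1e-12 of the largest are dropped with
    a warning; asking for more components than remain truncates with a
    warning rather than failing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    M = X.shape[0]
    if M < 2:
        raise ValueError("kernel PCA needs at least 2 training samples")
    K = kernel_matrix(X, X, sigma, kernel)
    Kc = center_kernel(K)
    evals, evecs = np.linalg.eigh(Kc)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    lam_max = max(float(evals[0]), 0.0)
    keep = evals > _EIG_TOL * lam_max if lam_max > 0 else np.zeros(M, dtype=bool)
    n_pos = int(keep.sum())
    if n_components is None:
        n_components = n_pos
    if n_components > n_pos:
        warnings.warn(
            f"requested {n_components} components but only {n_pos} have "
            f"non-negligible eigenvalues; truncating",
            stacklevel=2,
        )
        n_components = n_pos

    alphas = np.zeros((M, n_components))
    for k in range(n_components):
        v = evecs[:, k]
        # unit-norm feature-space eigenvector: lambda * (alpha . alpha) = 1
        a = v / np.sqrt(evals[k])
        # deterministic sign: largest-magnitude entry positive
        j = int(np.argmax(np.abs(a)))
        if a[j] < 0:
            a = -a
        alphas[:, k] = a
    return KPCAModel(X, sigma, kernel, K, Kc, evals, alphas, n_components)


def kpca_transform(model: KPCAModel, X_new) -> ScoreTable:
    """Project new samples onto the fitted components.

    Test kernel rows are centered against the training kernel statistics,
    so transforming the training matrix reproduces the training scores.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.training_features.shape[1]:
        raise ValueError(
            f"feature count mismatch: model expects {model.training_features.shape[1]}, "
            f"got {X_new.shape[1]}"
        )
    Kt = kernel_matrix(X_new, model.training_features, model.sigma, model.kernel)
    K = model.kernel_matrix
    col_mean = K.mean(axis=0)[None, :]
    row_mean = Kt.mean(axis=1, keepdims=True)
    grand = K.mean()
    Ktc = Kt - row_mean - col_mean + grand
    return ScoreTable(Ktc @ model.coefficients, model.explained_ratio)


def sigma_sweep(
    X_cal,
    y_cal,
    sigmas=DEFAULT_SIGMA_GRID,
    n_components: int = 5,
    downstream: dict | None = None,
    folds: int | None = None,
) -> pd.DataFrame:
    """RMSECV of a KPCA + regression pipeline across kernel widths.

    For each sigma the whole pipeline (KPCA fit, then the downstream
    regressor on the scores) is refit inside every cross-validation fold;
    held-out samples are projected with :func:`kpca_transform`.  Failures
    at a single sigma are recorded as NaN and the sweep continues.
    Returns a DataFrame with columns ``sigma`` and ``rmsecv`` sorted by
    sigma (duplicates deduplicated with a warning).
    """
    from .regression import pls_fit, mlr_fit, rmsecv  # deferred: avoids cycle

    sigmas = [float(s) for s in sigmas]
    if len(sigmas) < 2:
        raise ValueError("sigma sweep needs at least 2 sigma values")
    unique = sorted(set(sigmas))
    if len(unique) < len(sigmas):
        warnings.warn("duplicate sigma values removed from sweep", stacklevel=2)
    downstream = dict(downstream or {"method": "pls", "n_latent": 3})
    method = downstream.get("method", "pls")

    def make_factory(sigma):
        def factory(X_tr, y_tr):
            model = kpca_fit(X_tr, sigma=sigma, n_components=n_components)
            scores = model.training_scores
            if method == "pls":
                n_latent = min(
                    downstream.get("n_latent", 3), model.n_components, len(y_tr) - 1
                )
                reg = pls_fit(scores, y_tr, max(n_latent, 1))
            elif method == "mlr":
                reg = mlr_fit(scores, y_tr)
            else:
                raise ValueError(f"unknown downstream method {method!r}")

            def predict(X_te):
                return reg.predict(kpca_transform(model, X_te).scores)

            return predict

        return factory

    rows = []
    for sigma in unique:
        try:
            val = rmsecv(X_cal, y_cal, make_factory(sigma), folds=folds)
        except Exception as exc:  # a single bad sigma must not kill the sweep
            warnings.warn(f"sigma {sigma} failed: {exc}", stacklevel=2)
            val = float("nan")
        rows.append({"sigma": sigma, "rmsecv": val})
        logger.info("sigma sweep: sigma=%g rmsecv=%s", sigma, rows[-1]["rmsecv"])
    return pd.DataFrame(rows)
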