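"""Spectral preprocessing: averaging, smoothing, baseline correction,
derivatives and feature-range extraction.

The default chain follows the usual narration order of a SERS quantitation
workflow — average replicates, Savitzky-Golay smooth, subtract a fitted
baseline, optionally differentiate, then cut out the configured feature
ranges.  Smoothing precedes differentiation because differentiation
amplifies high-frequency noise.

Baseline estimation offers two standard methods:

* ``poly-iterative`` — modified polynomial fitting (modpoly): fit a
  polynomial, clip the working signal to the fit's minimum, iterate until
  the working signal stabilises.  Peaks are progressively excluded, leaving
  the smooth background.
* ``als`` — asymmetric least squares (Whittaker smoother with asymmetric
  weights): penalised least squares where points above the baseline get
  weight ``p`` and points below get ``1 - p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .io import Spectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "average_spectra",
    "smooth",
    "correct_baseline",
    "estimate_baseline",
    "derivative",
    "extract_ranges",
    "preprocess_set",
]

DEFAULT_FEATURE_RANGES = ((653.0, 683.0), (705.0, 728.0), (847.0, 872.0))


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    smooth_window must be odd and larger than smooth_polyorder;
    derivative_order 0 means "no differentiation".
    """

    smooth_window: int = 9
    smooth_polyorder: int = 3
    baseline_method: str = "poly-iterative"
    baseline_degree: int = 5
    baseline_max_iter: int = 50
    baseline_tol: float = 1e-4
    als_lambda: float = 1e5
    als_p: float = 0.01
    als_max_iter: int = 10
    derivative_order: int = 0
    feature_ranges: tuple = DEFAULT_FEATURE_RANGES

    def __post_init__(self):
        if self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        if self.smooth_window <= self.smooth_polyorder:
            raise ValueError("smooth_window must exceed smooth_polyorder")
        if self.baseline_method not in ("poly-iterative", "als"):
            raise ValueError(f"unknown baseline method {self.baseline_method!r}")
        if self.derivative_order not in (0, 1, 2):
            raise ValueError("derivative_order must be 0, 1 or 2")
        ranges = [(float(lo), float(hi)) for lo, hi in self.feature_ranges]
        for lo, hi in ranges:
            if lo >= hi:
                raise ValueError(f"feature range ({lo}, {hi}) is empty")
        for (a, b), (c, d) in zip(ranges, ranges[1:]):
            if c <= b:
                raise ValueError("feature ranges must be sorted and non-overlapping")
        self.feature_ranges = tuple(ranges)


def average_spectra(sset: SpectrumSet, by: str = "group") -> SpectrumSet:
    """Average replicate spectra within each group (axis unchanged).

    ``by='group'`` uses the set's group labels; any per-sample list of
    labels may be passed instead.  Group order follows first appearance.
    """
    if isinstance(by, str):
        if by != "group":
            raise ValueError("by must be 'group' or an explicit label sequence")
        if sset.groups is None:
            raise ValueError("SpectrumSet has no group labels to average by")
        labels = list(sset.groups)
    else:
        labels = [str(x) for x in by]
        if len(labels) != len(sset):
            raise ValueError("one label required per spectrum")
    order = list(dict.fromkeys(labels))
    means, concs = [], []
    for g in order:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        if not idx:
            raise ValueError(f"group {g!r} is empty")
        means.append(sset.intensities[idx].mean(axis=0))
        if sset.concentrations is not None:
            concs.append(float(np.mean(sset.concentrations[idx])))
    return SpectrumSet(
        sset.wavenumbers,
        np.vstack(means),
        order,
        np.array(concs) if concs else None,
        sset.unit,
        order,
    )


def smooth(spectrum: Spectrum, window: int = 9, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay least-squares polynomial smoothing."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > len(spectrum):
        raise ValueError("window exceeds spectrum length")
    out = savgol_filter(spectrum.intensities, window, polyorder, mode="interp")
    return Spectrum(spectrum.wavenumbers, out, spectrum.sample_id)


def _modpoly_baseline(nu, y, degree, max_iter, tol):
    work = y.astype(float).copy()
    base = work
    for _ in range(max_iter):
        poly = np.polynomial.Polynomial.fit(nu, work, degree)
        base = poly(nu)
        clipped = np.minimum(work, base)
        denom = np.linalg.norm(work)
        crit = np.linalg.norm(clipped - work) / denom if denom > 0 else 0.0
        work = clipped
        if crit < tol:
            break
    return base


def _als_baseline(y, lam, p, max_iter):
    n = y.shape[0]
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    penalty = lam * (d @ d.T)
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        W = sparse.diags(w)
        z = spsolve((W + penalty).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def estimate_baseline(spectrum: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Estimate the smooth background under a spectrum."""
    cfg = cfg or PreprocessConfig()
    if cfg.baseline_method == "poly-iterative":
        base = _modpoly_baseline(
            spectrum.wavenumbers,
            spectrum.intensities,
            cfg.baseline_degree,
            cfg.baseline_max_iter,
            cfg.baseline_tol,
        )
    else:
        base = _als_baseline(
            spectrum.intensities, cfg.als_lambda, cfg.als_p, cfg.als_max_iter
        )
    return Spectrum(spectrum.wavenumbers, base, spectrum.sample_id)


def correct_baseline(spectrum: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Subtract the estimated baseline from a spectrum."""
    base = estimate_baseline(spectrum, cfg)
    return Spectrum(
        spectrum.wavenumbers, spectrum.intensities - base.intensities, spectrum.sample_id
    )


def _uniform_step(nu: np.ndarray) -> float:
    steps = np.diff(nu)
    step = float(steps.mean())
    if not np.allclose(steps, step, rtol=1e-6, atol=1e-9 * abs(step)):
        raise ValueError("derivatives require a uniformly spaced wavenumber axis")
    return step


def derivative(
    spectrum: Spectrum, order: int, window: int = 9, polyorder: int = 3
) -> Spectrum:
    """Savitzky-Golay derivative with respect to wavenumber.

    Order 1 annihilates a constant offset; order 2 additionally annihilates
    a linear ramp — the standard drift-removal rationale.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    polyorder = max(polyorder, order)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    step = _uniform_step(spectrum.wavenumbers)
    out = savgol_filter(
        spectrum.intensities, window, polyorder, deriv=order, delta=step, mode="interp"
    )
    return Spectrum(spectrum.wavenumbers, out, spectrum.sample_id)


def extract_ranges(spectrum: Spectrum, ranges=DEFAULT_FEATURE_RANGES):
    """Concatenate intensities whose wavenumbers fall in the closed ranges.

    Returns ``(sub_axis, values)`` with axis order preserved.  A range that
    contains no axis point is an error naming the range.
    """
    nu = spectrum.wavenumbers
    mask = np.zeros(nu.shape, dtype=bool)
    for lo, hi in ranges:
        if lo > hi:
            raise ValueError(f"range ({lo}, {hi}) is empty")
        hit = (nu >= lo) & (nu <= hi)
        if not hit.any():
            raise ValueError(f"range ({lo}, {hi}) lies outside the wavenumber axis")
        mask |= hit
    return nu[mask], spectrum.intensities[mask]


def preprocess_set(
    sset: SpectrumSet,
    cfg: PreprocessConfig | None = None,
    average_by: str | None = None,
) -> SpectrumSet:
    """Apply the default chain (average -> smooth -> baseline -> derivative).

    Feature-range extraction is a separate step (:func:`extract_ranges`)
    because it changes the axis.
    """
    cfg = cfg or PreprocessConfig()
    if average_by is not None:
        sset = average_spectra(sset, by=average_by)
    out = []
    for spec in sset:
        s = smooth(spec, cfg.smooth_window, cfg.smooth_polyorder)
        s = correct_baseline(s, cfg)
        if cfg.derivative_order:
            s = derivative(
                s, cfg.derivative_order, cfg.smooth_window, cfg.smooth_polyorder
            )
        out.append(s)
    return SpectrumSet(
        sset.wavenumbers,
        np.vstack([s.intensities for s in out]),
        sset.sample_ids,
        sset.concentrations,
        sset.unit,
        sset.groups,
    )
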