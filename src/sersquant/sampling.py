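"""Deterministic max-min calibration/prediction set partitioning.

A Kennard-Stone-like scheme that seeds the calibration set with the two
samples at minimum and maximum Euclidean distance from the mean spectrum,
then repeatedly computes each remaining sample's minimum distance to the
current calibration set and admits both the farthest and the nearest sample
per iteration (one only when one slot remains).  The farthest-first element
spans the feature space; the nearest-first element keeps interior density.
Ties break toward the lowest input index, so the split is fully
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import SpectrumSet

logger = logging.getLogger(__name__)

__all__ = ["SplitResult", "maxmin_split"]


@dataclass
class SplitResult:
    """Outcome of a max-min split.

    ``distances_log`` records one (step, kind, index, distance) tuple per
    selection for auditability: kind is 'seed-min', 'seed-max', 'iter-max'
    or 'iter-min'.
    """

    calibration_indices: list[int]
    prediction_indices: list[int]
    calibration_ids: list[str]
    prediction_ids: list[str]
    distances_log: list[tuple]


def _feature_matrix(data):
    if isinstance(data, SpectrumSet):
        return np.asarray(data.intensities, dtype=float), list(data.sample_ids)
    X = np.atleast_2d(np.asarray(data, dtype=float))
    return X, [str(i) for i in range(X.shape[0])]


def maxmin_split(data, n_cal: int | None = None) -> SplitResult:
    """Partition samples into calibration and prediction sets.

    ``data`` is a SpectrumSet or an (n_samples, n_features) matrix.  When
    ``n_cal`` is omitted a 3:1 calibration:prediction ratio is used.
    Requires 2 <= n_cal <= n_samples - 1.
    """
    X, ids = _feature_matrix(data)
    n = X.shape[0]
    if n_cal is None:
        n_cal = min(max(2, int(round(0.75 * n))), n - 1)
    if not 2 <= n_cal <= n - 1:
        raise ValueError(f"n_cal must lie in [2, {n - 1}], got {n_cal}")

    log: list[tuple] = []
    mean = X.mean(axis=0)
    d_mean = np.linalg.norm(X - mean, axis=1)

    cal: list[int] = []
    i_min = int(np.argmin(d_mean))
    cal.append(i_min)
    log.append((0, "seed-min", i_min, float(d_mean[i_min])))
    rest = np.array([i for i in range(n) if i not in cal])
    i_max = int(rest[np.argmax(d_mean[rest])])
    cal.append(i_max)
    log.append((0, "seed-max", i_max, float(d_mean[i_max])))
    logger.info("max-min seed: min-distance sample %d, max-distance sample %d", i_min, i_max)

    step = 0
    while len(cal) < n_cal:
        step += 1
        rest = np.array([i for i in range(n) if i not in cal])
        # per-candidate minimum Euclidean distance to the calibration set;
        # computed once per iteration (the subsequent argmin uses the same
        # vector, the just-added argmax merely drops out of the candidates)
        diff = X[rest][:, None, :] - X[cal][None, :, :]
        d = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
        j_max = int(np.argmax(d))
        pick_max = int(rest[j_max])
        cal.append(pick_max)
        log.append((step, "iter-max", pick_max, float(d[j_max])))
        if len(cal) < n_cal:
            keep = np.ones(rest.shape[0], dtype=bool)
            keep[j_max] = False
            if keep.any():
                sub = np.flatnonzero(keep)
                j_min = int(sub[np.argmin(d[sub])])
                pick_min = int(rest[j_min])
                cal.append(pick_min)
                log.append((step, "iter-min", pick_min, float(d[j_min])))
        logger.info("max-min iteration %d: calibration size %d", step, len(cal))

    pred = [i for i in range(n) if i not in cal]
    return SplitResult(
        calibration_indices=cal,
        prediction_indices=pred,
        calibration_ids=[ids[i] for i in cal],
        prediction_ids=[ids[i] for i in pred],
        distances_log=log,
    )
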