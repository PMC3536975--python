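"""Smoothness-priors detrending and per-voxel z-normalization.

Low-frequency drift is removed by subtracting the trend that solves the
second-difference-regularized least-squares problem

    trend = (I + lambda^2 D2' D2)^{-1} y

with regularization parameter lambda = 200 by default. At the end of the
localizer the complete series of every selected voxel is detrended in batch
and a per-voxel baseline (mean) and scale (standard deviation) are frozen;
during control each new volume is detrended causally over a trailing window
of the kept raw history and normalized with the frozen statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve_banded, cholesky_banded


@dataclass(frozen=True)
class DetrendConfig:
    lambda_reg: float = 200.0
    control_window: int = 100

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.control_window < 10:
            raise ValueError("control_window must be >= 10")


_factor_cache: dict[tuple[int, float], np.ndarray] = {}


def _banded_factor(T: int, lam: float) -> np.ndarray:
    """Cholesky factor (banded, lower form) of I + lam^2 D2'D2."""
    key = (T, float(lam))
    if key not in _factor_cache:
        D = np.zeros((3, T))  # D2 rows as banded stencil
        # build A = I + lam^2 D2'D2 directly in banded lower storage
        A = np.zeros((3, T))
        # dense pentadiagonal entries of D2'D2 for the (T-2)xT operator
        d0 = np.zeros(T)
        d1 = np.zeros(T - 1)
        d2 = np.zeros(T - 2)
        # row i of D2 is [.. 1 -2 1 ..] at columns i, i+1, i+2
        for i in range(T - 2):
            d0[i] += 1.0
            d0[i + 1] += 4.0
            d0[i + 2] += 1.0
            d1[i] += -2.0
            d1[i + 1] += -2.0
            d2[i] += 1.0
        A[0] = 1.0 + lam**2 * d0
        A[1, : T - 1] = lam**2 * d1
        A[2, : T - 2] = lam**2 * d2
        _factor_cache[key] = cholesky_banded(A, lower=True)
        del D
    return _factor_cache[key]


def smoothness_trend(series: np.ndarray, lambda_reg: float) -> np.ndarray:
    """The estimated low-frequency trend of ``series`` (1-D or (T, n))."""
    y = np.asarray(series, dtype=float)
    one_d = y.ndim == 1
    if one_d:
        y = y[:, None]
    T = y.shape[0]
    if T < 3:
        raise ValueError("detrending needs at least 3 samples")
    if lambda_reg == 0:
        trend = y.copy()
    else:
        cb = _banded_factor(T, lambda_reg)
        trend = cho_solve_banded((cb, True), y)
    return trend[:, 0] if one_d else trend


def detrend_batch(series: np.ndarray, lambda_reg: float = 200.0) -> np.ndarray:
    """Series minus its smoothness-priors trend.

    An exactly linear series detrends to zero (its second differences
    vanish, so the trend reproduces it); lambda = 0 returns all zeros.
    """
    y = np.asarray(series, dtype=float)
    return y - smoothness_trend(y, lambda_reg)


class VoxelNormalizer:
    """Frozen per-voxel baseline/scale plus the kept raw history.

    Fit on the batch-detrended localizer series of the masked voxels;
    never updated during control. Raw (non-detrended) values are retained
    so later volumes can be detrended over a trailing window.
    """

    def __init__(
        self,
        baseline: np.ndarray,
        scale: np.ndarray,
        raw_history: np.ndarray,
        config: DetrendConfig,
    ):
        if np.any(scale <= 0):
            raise ValueError(
                "zero-variance voxel reached the normalizer; exclude it upstream"
            )
        self.baseline = np.asarray(baseline, dtype=float)
        self.scale = np.asarray(scale, dtype=float)
        self.raw_history = np.asarray(raw_history, dtype=float)  # (T, n_voxels)
        self.config = config

    @property
    def n_voxels(self) -> int:
        return self.baseline.size

    def normalize(self, detrended: np.ndarray) -> np.ndarray:
        return (detrended - self.baseline) / self.scale

    def process_control_volume(self, raw_values: np.ndarray) -> np.ndarray:
        """Detrend-and-normalize one control volume's masked values.

        Appends the raw values to the history, re-solves the smoothness
        prior on the trailing ``control_window`` samples, takes the newest
        detrended sample and z-scores it with the frozen statistics.
        """
        v = np.asarray(raw_values, dtype=float).ravel()
        if v.shape != (self.n_voxels,):
            raise ValueError("raw value count does not match the mask")
        self.raw_history = np.vstack([self.raw_history, v[None, :]])
        w = min(self.config.control_window, self.raw_history.shape[0])
        window = self.raw_history[-w:]
        detrended = detrend_batch(window, self.config.lambda_reg)
        return self.normalize(detrended[-1])


def fit_normalizer(
    localizer_series: np.ndarray, config: DetrendConfig = DetrendConfig()
) -> tuple[VoxelNormalizer, np.ndarray]:
    """Fit the per-voxel normalizer on the complete localizer series.

    ``localizer_series`` is (T, n_voxels) raw masked values. Returns the
    normalizer and the detrended-and-normalized training series (used for
    SVM training), which has mean 0 and unit variance per voxel.

    Raises if any voxel has zero variance after detrending; such voxels
    must be removed from the mask before fitting.
    """
    raw = np.asarray(localizer_series, dtype=float)
    if raw.ndim != 2:
        raise ValueError("localizer_series must be (T, n_voxels)")
    detrended = detrend_batch(raw, config.lambda_reg)
    baseline = detrended.mean(axis=0)
    scale = detrended.std(axis=0)
    bad = np.flatnonzero(_is_degenerate(raw, scale))
    if bad.size:
        raise ValueError(
            f"{bad.size} zero-variance voxels (first indices {bad[:5].tolist()}); "
            "exclude them from the mask"
        )
    norm = VoxelNormalizer(baseline, scale, raw, config)
    return norm, norm.normalize(detrended)


def _is_degenerate(raw: np.ndarray, detrended_scale: np.ndarray) -> np.ndarray:
    """Voxels whose detrended variance is zero up to solve round-off
    (constant or exactly-linear raw series)."""
    ref = raw.std(axis=0) + np.abs(raw).max(axis=0) + 1.0
    return detrended_scale <= 1e-9 * ref


def zero_variance_voxels(
    localizer_series: np.ndarray, config: DetrendConfig = DetrendConfig()
) -> np.ndarray:
    """Column indices whose detrended localizer series has zero variance."""
    raw = np.asarray(localizer_series, float)
    detrended = detrend_batch(raw, config.lambda_reg)
    return np.flatnonzero(_is_degenerate(raw, detrended.std(axis=0)))
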