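"""Incrementally updated per-voxel GLM and contrast t-maps.

The design has five regressors — right, left, up and center attention plus
a linear drift term. Sufficient statistics (X'X, X'y, y'y) are accumulated
by rank-1 updates with every new volume, so t-maps can be produced at any
point without storing the image history; the result is algebraically
identical to a batch least-squares fit on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from covisa.simulate import ALL_DIRECTIONS, CueSchedule, Hrf, attention_regressors

REGRESSOR_NAMES = ("right", "left", "up", "center", "drift")
N_REGRESSORS = 5


@dataclass(frozen=True)
class Contrast:
    """A weighting of the five regression coefficients; drift weight is
    always zero and the four attention weights sum to zero."""

    name: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_REGRESSORS,):
            raise ValueError("contrast must have 5 weights")
        if w[4] != 0.0:
            raise ValueError("drift weight must be 0")
        if abs(w[:4].sum()) > 1e-12:
            raise ValueError("attention weights must sum to 0")
        object.__setattr__(self, "weights", w)


def standard_contrasts() -> list[Contrast]:
    """The four 'one minus the others' contrasts, e.g. for right attention
    right - (left + up + center)/3."""
    out = []
    for i, d in enumerate(ALL_DIRECTIONS):
        w = np.full(N_REGRESSORS, -1.0 / 3.0)
        w[i] = 1.0
        w[4] = 0.0
        out.append(Contrast(d.value, w))
    return out


def design_matrix(
    schedule: CueSchedule, hrf: Hrf, n_volumes: int, convolve: bool = True
) -> np.ndarray:
    """Localizer design: four attention regressors and a linear ramp.

    ``convolve=False`` uses raw boxcars instead of HRF-convolved responses.
    """
    regs, ramp = attention_regressors(
        schedule, hrf if convolve else Hrf(kernel=np.array([1.0]), lag_volumes=0), n_volumes
    )
    X = np.column_stack([regs[d] for d in ALL_DIRECTIONS] + [ramp])
    return X


class GlmState:
    """Per-voxel recursive least-squares sufficient statistics.

    Stores the 5x5 design cross-product, per-voxel X'y accumulators and
    response sums of squares. ``beta``/``rss``/``t_map`` solve on demand and
    equal a from-scratch batch fit on the same rows.
    """

    def __init__(self, n_voxels: int):
        if n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        self.n_voxels = n_voxels
        self.n_seen = 0
        self.xtx = np.zeros((N_REGRESSORS, N_REGRESSORS))
        self.xty = np.zeros((N_REGRESSORS, n_voxels))
        self.yty = np.zeros(n_voxels)

    @property
    def dof(self) -> int:
        return self.n_seen - N_REGRESSORS

    def update(self, design_row: np.ndarray, voxel_values: np.ndarray) -> "GlmState":
        """Rank-1 accumulator update with one volume's data (in place)."""
        x = np.asarray(design_row, dtype=float)
        y = np.asarray(voxel_values, dtype=float).ravel()
        if x.shape != (N_REGRESSORS,):
            raise ValueError("design_row must have 5 entries")
        if y.shape != (self.n_voxels,):
            raise ValueError(
                f"expected {self.n_voxels} voxel values, got {y.shape[0]}"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite input rejected")
        self.xtx += np.outer(x, x)
        self.xty += np.outer(x, y)
        self.yty += y * y
        self.n_seen += 1
        return self

    def _solve(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
        """Return (beta, rss, xtx_inv, used_pinv)."""
        try:
            xtx_inv = np.linalg.inv(self.xtx)
            used_pinv = False
        except np.linalg.LinAlgError:
            xtx_inv = np.linalg.pinv(self.xtx)
            used_pinv = True
        beta = xtx_inv @ self.xty
        rss = self.yty - np.einsum("kv,kv->v", self.xty, beta)
        # exact fits leave only cancellation residue; clamp to true zero
        rss[rss <= 1e-12 * self.yty] = 0.0
        rss = np.maximum(rss, 0.0)
        return beta, rss, xtx_inv, used_pinv

    @property
    def beta(self) -> np.ndarray:
        """(5, n_voxels) least-squares coefficients."""
        return self._solve()[0]

    @property
    def rss(self) -> np.ndarray:
        """Per-voxel residual sum of squares."""
        return self._solve()[1]

    def t_map(self, contrast: Contrast) -> np.ndarray:
        """Per-voxel t statistic of ``contrast``.

        t = w'beta / sqrt((rss/dof) * w'(X'X)^-1 w). Voxels with zero
        residual variance map to a sign-matched infinite sentinel.
        """
        if self.dof < 1:
            raise ValueError(f"t_map needs dof >= 1, have {self.dof}")
        w = contrast.weights
        beta, rss, xtx_inv, _ = self._solve()
        effect = w @ beta
        wvw = float(w @ xtx_inv @ w)
        if wvw <= 0.0:
            return np.zeros(self.n_voxels)
        denom = np.sqrt((rss / self.dof) * wvw)
        t = np.zeros(self.n_voxels)
        ok = denom > 0
        t[ok] = effect[ok] / denom[ok]
        exact = (~ok) & (effect != 0)
        t[exact] = np.sign(effect[exact]) * np.inf
        return t
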