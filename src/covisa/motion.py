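"""Rigid-body motion correction for streaming volumes.

Every incoming volume is rigidly registered to the first localizer volume by
minimizing the sum of squared differences between Gaussian-smoothed images
(sigma = 1 voxel) with a fixed number of stochastic gradient descent
iterations, then resampled with interpolating cubic B-splines.

The transform maps template world coordinates to moving-image world
coordinates (pull-back convention), with world = voxel index * voxel size
and rotation about the volume center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


def _euler_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid transform: Euler angles (radians) and
    translation (mm), rotating about ``center`` (mm; volume center if None)."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] | None = None

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def is_identity(self) -> bool:
        return all(p == 0.0 for p in self.rotation + self.translation)

    @property
    def params(self) -> np.ndarray:
        return np.array(self.rotation + self.translation, dtype=float)

    @classmethod
    def from_params(
        cls, params: np.ndarray, center: tuple[float, float, float] | None = None
    ) -> "RigidTransform":
        p = np.asarray(params, dtype=float)
        return cls(tuple(p[:3]), tuple(p[3:6]), center)

    def matrix(self) -> np.ndarray:
        return _euler_matrix(*self.rotation)

    def apply_points(self, pts: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Map (N, 3) world points through the transform."""
        c = np.asarray(self.center if self.center is not None else center)
        R = self.matrix()
        t = np.asarray(self.translation)
        return (pts - c) @ R.T + c + t

    def inverse(self) -> "RigidTransform":
        """Exact inverse (same rotation center)."""
        R = self.matrix()
        t = np.asarray(self.translation)
        Rinv = R.T
        # x' = R(x-c)+c+t  =>  x = R^T(x'-c-t)+c; rewrite about the same c:
        # x = R^T(x'-c) + c + (R^T(-t)) since R^T(x'-c-t)+c = R^T(x'-c)+c-R^T t
        rx, ry, rz = _matrix_to_euler(Rinv)
        tinv = tuple((-Rinv @ t).tolist())
        return RigidTransform((rx, ry, rz), tinv, self.center)


def _matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    # inverse of Rz @ Ry @ Rx
    sy = -R[2, 0]
    sy = np.clip(sy, -1.0, 1.0)
    ry = np.arcsin(sy)
    if abs(np.cos(ry)) > 1e-8:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:  # gimbal lock; negligible for head-motion magnitudes
        rx = np.arctan2(-R[1, 2], R[1, 1])
        rz = 0.0
    return float(rx), float(ry), float(rz)


@dataclass(frozen=True)
class RegistrationConfig:
    """Optimizer settings for rigid registration.

    Defaults follow the online pipeline: Gaussian smoothing with sigma of
    one voxel before metric evaluation and exactly 50 stochastic gradient
    descent iterations. The gain sequence gain_a/(gain_A + k)^gain_alpha and
    the per-iteration voxel subsample size are engineering choices.
    """

    smoothing_sigma_voxels: float = 1.0
    iterations: int = 50
    samples_per_iteration: int = 2048
    gain_a: float = 3.0
    gain_A: float = 10.0
    gain_alpha: float = 0.602

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.smoothing_sigma_voxels < 0:
            raise ValueError("smoothing sigma must be >= 0")
        if self.samples_per_iteration < 1:
            raise ValueError("samples_per_iteration must be >= 1")


class RegistrationDegenerateError(ValueError):
    """Template has no intensity structure to register against."""


def _world_grid(shape: tuple[int, ...], voxel_mm: tuple[float, float, float]):
    s = np.asarray(voxel_mm, dtype=float)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0 * s
    return s, center


def apply_rigid(
    volume: np.ndarray,
    transform: RigidTransform,
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    order: int = 3,
) -> np.ndarray:
    """Resample ``volume`` onto the template grid under ``transform``.

    Uses the interpolating cubic B-spline (spline prefilter), so grid points
    are exactly reproduced under the identity transform; out-of-field
    voxels are filled with 0.
    """
    if not np.all(np.isfinite(transform.params)):
        raise ValueError("transform parameters must be finite")
    if transform.is_identity():
        return volume.astype(float, copy=True)
    s, default_center = _world_grid(volume.shape, voxel_mm)
    c = np.asarray(
        transform.center if transform.center is not None else default_center
    )
    R = transform.matrix()
    t = np.asarray(transform.translation)
    S = np.diag(s)
    Sinv = np.diag(1.0 / s)
    # output index i_out -> input index: S^-1 (R (S i - c) + c + t)
    M = Sinv @ R @ S
    offset = Sinv @ ((np.eye(3) - R) @ c + t)
    return ndimage.affine_transform(
        volume.astype(float),
        M,
        offset=offset,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=True,
    )


def resample(
    volume: np.ndarray,
    transform: RigidTransform,
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Cubic B-spline resampling of a motion-corrupted volume back onto the
    template grid (alias of :func:`apply_rigid` at order 3)."""
    return apply_rigid(volume, transform, voxel_mm, order=3)


def register(
    moving: np.ndarray,
    template: np.ndarray,
    config: RegistrationConfig = RegistrationConfig(),
    seed: int = 0,
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` to ``template``.

    Minimizes the sum of squared differences between Gaussian-smoothed
    images by stochastic gradient descent: each iteration draws a random
    subsample of template voxels, evaluates the metric gradient there
    analytically (chain rule through the interpolated moving image), and
    takes a step with decaying gain. Deterministic given ``seed``.
    """
    if moving.shape != template.shape:
        raise ValueError("moving and template must share the same grid")
    if not np.isfinite(template).all() or float(np.ptp(template)) == 0.0:
        raise RegistrationDegenerateError(
            "template is constant or non-finite; nothing to register against"
        )
    sigma = config.smoothing_sigma_voxels
    tpl = ndimage.gaussian_filter(template.astype(float), sigma) if sigma > 0 else template.astype(float)
    mov = ndimage.gaussian_filter(moving.astype(float), sigma) if sigma > 0 else moving.astype(float)
    grad = np.stack(np.gradient(mov, *voxel_mm), axis=0)  # d(mov)/d(world mm)

    s, center = _world_grid(template.shape, voxel_mm)
    rng = np.random.default_rng(seed)

    # sample the full grid: restricting to template-body voxels would leave
    # moving-image structure over template background unpenalized and shift
    # the metric's minimum
    body = np.arange(tpl.size)

    scale = float(np.ptp(tpl))
    # parameter scaling: radians vs mm live on different natural scales;
    # normalize gradient by intensity range^2 and typical lever arm
    lever = float(np.linalg.norm(np.asarray(template.shape) * s)) / 4.0
    p = np.zeros(6)
    g_ref = 0.0  # running peak gradient norm, for relative step damping

    idx_cache = np.array(np.unravel_index(body, template.shape)).T  # (Nbody, 3)
    world_cache = idx_cache * s

    for k in range(config.iterations):
        n = min(config.samples_per_iteration, body.size)
        pick = rng.choice(body.size, size=n, replace=False)
        pts = world_cache[pick]
        f = tpl.ravel()[body[pick]]

        tr = RigidTransform.from_params(p)
        mapped = tr.apply_points(pts, center)
        coords = (mapped / s).T  # index coordinates in moving image
        m = ndimage.map_coordinates(mov, coords, order=1, mode="constant", cval=0.0)
        g = np.stack(
            [ndimage.map_coordinates(grad[a], coords, order=1, mode="constant", cval=0.0) for a in range(3)],
            axis=1,
        )  # (n, 3) spatial gradient at mapped points

        diff = (m - f)[:, None]  # (n, 1)
        # derivative of mapped point w.r.t. parameters
        rel = pts - center
        rx, ry, rz = p[:3]
        R = _euler_matrix(rx, ry, rz)
        eps = 1e-6
        dR = []
        for a in range(3):
            dp = p[:3].copy()
            dp[a] += eps
            dR.append((_euler_matrix(*dp) - R) / eps)
        J = np.empty((n, 3, 6))
        for a in range(3):
            J[:, :, a] = rel @ dR[a].T
        J[:, :, 3:] = np.broadcast_to(np.eye(3), (n, 3, 3))

        grad_p = 2.0 * np.einsum("ni,nia->a", diff * g / (scale**2), J) / n
        # precondition so a unit step moves points ~1 mm whether it comes
        # from an angle or a translation, then take a normalized step of
        # decaying length (gain_a is the initial step in mm)
        gs = grad_p.copy()
        gs[:3] *= lever
        norm = float(np.linalg.norm(gs))
        if norm < 1e-12:  # already aligned (e.g. self-registration)
            continue
        g_ref = max(g_ref, norm)
        gain = config.gain_a / (config.gain_A + k + 1) ** config.gain_alpha
        # full normalized step while the gradient is near its peak; once in
        # the convergence basin the gradient (hence the step) shrinks with
        # the residual misalignment, suppressing the stochastic jitter floor
        gain *= min(1.0, norm / (0.2 * g_ref))
        step = gs / norm * gain
        step[:3] /= lever
        p = p - step

    return RigidTransform.from_params(p)


def smoothed_ssd(
    a: np.ndarray,
    b: np.ndarray,
    sigma: float = 1.0,
) -> float:
    """Mean squared difference between Gaussian-smoothed volumes (the
    registration objective, exposed for diagnostics and tests)."""
    fa = ndimage.gaussian_filter(a.astype(float), sigma) if sigma > 0 else a
    fb = ndimage.gaussian_filter(b.astype(float), sigma) if sigma > 0 else b
    return float(np.mean((fa - fb) ** 2))


def correct_volume(
    volume: np.ndarray,
    template: np.ndarray,
    config: RegistrationConfig = RegistrationConfig(),
    seed: int = 0,
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[np.ndarray, RigidTransform]:
    """Register then resample one volume; returns the corrected volume and
    the estimated transform (logged per volume in the session log)."""
    t = register(volume, template, config, seed=seed, voxel_mm=voxel_mm)
    return resample(volume, t, voxel_mm), t
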