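"""Synthetic BCI session generator.

Stands in for the 7T scanner and the human subject: builds the localizer cue
schedule, hemodynamic regressors, a digital phantom with attention-responsive
voxel clusters, and streams 4D volumes with BOLD dynamics, low-frequency
drift, white noise and optional rigid head motion. Every source of
randomness is seeded, so a session regenerates bit-identically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from covisa.motion import RigidTransform, apply_rigid


class Direction(str, enum.Enum):
    """Covert attention target; CENTER is the resting/no-command state."""

    RIGHT = "right"
    LEFT = "left"
    UP = "up"
    CENTER = "center"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The three command-issuing directions (CENTER never moves the robot).
COMMAND_DIRECTIONS = (Direction.RIGHT, Direction.LEFT, Direction.UP)
#: Regressor/class order used throughout: right, left, up, center.
ALL_DIRECTIONS = (Direction.RIGHT, Direction.LEFT, Direction.UP, Direction.CENTER)


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition geometry and phase timing.

    Defaults reproduce the study protocol: a single 995-volume EPI run
    (270 localizer + 725 control volumes) at TR = 1.62 s, 96x96 matrix with
    35 slices, 1.848 x 1.848 x 2 mm voxels, 5-volume attention trials.
    """

    tr_seconds: float = 1.62
    n_localizer: int = 270
    n_control: int = 725
    matrix: tuple[int, int, int] = (96, 96, 35)
    voxel_mm: tuple[float, float, float] = (1.848, 1.848, 2.0)
    trial_len: int = 5

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_localizer <= 0 or self.n_control < 0:
            raise ValueError("phase lengths must be positive")
        if any(m <= 0 for m in self.matrix) or any(v <= 0 for v in self.voxel_mm):
            raise ValueError("matrix and voxel dimensions must be positive")
        if self.trial_len <= 0:
            raise ValueError("trial_len must be positive")

    @property
    def n_total(self) -> int:
        return self.n_localizer + self.n_control

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_mm))

    def toy(self) -> "ScanProtocol":
        """Same timing on a small 24x24x12 grid (fast tests and demos)."""
        return ScanProtocol(
            tr_seconds=self.tr_seconds,
            n_localizer=self.n_localizer,
            n_control=self.n_control,
            matrix=(24, 24, 12),
            voxel_mm=self.voxel_mm,
            trial_len=self.trial_len,
        )


@dataclass(frozen=True)
class Trial:
    direction: Direction
    start_volume: int
    length_volumes: int

    @property
    def volumes(self) -> range:
        return range(self.start_volume, self.start_volume + self.length_volumes)


@dataclass(frozen=True)
class CueSchedule:
    """Ordered localizer trials tiling the localizer phase with no gaps.

    Directional trials (right/left/up) are always separated by a center
    trial, and their counts are balanced to within one.
    """

    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        pos = 0
        prev_dir: Direction | None = None
        for t in self.trials:
            if t.start_volume != pos:
                raise ValueError("trials must tile the localizer phase with no gaps")
            if (
                prev_dir is not None
                and prev_dir != Direction.CENTER
                and t.direction != Direction.CENTER
            ):
                raise ValueError("directional trials must be separated by CENTER")
            prev_dir = t.direction
            pos += t.length_volumes
        counts = self.direction_counts()
        cmds = [counts[d] for d in COMMAND_DIRECTIONS]
        if max(cmds) - min(cmds) > 1:
            raise ValueError("directional trial counts must be balanced to within 1")

    @property
    def n_volumes(self) -> int:
        last = self.trials[-1]
        return last.start_volume + last.length_volumes

    def direction_counts(self) -> dict[Direction, int]:
        counts = {d: 0 for d in ALL_DIRECTIONS}
        for t in self.trials:
            counts[t.direction] += 1
        return counts

    def states(self) -> list[Direction]:
        """Per-volume attention state over the localizer phase."""
        out: list[Direction] = []
        for t in self.trials:
            out.extend([t.direction] * t.length_volumes)
        return out


def build_cue_schedule(protocol: ScanProtocol, seed: int) -> CueSchedule:
    """Build the localizer cue schedule.

    Trials alternate CENTER / directional starting with CENTER; directional
    labels are a balanced randomized sequence of right/left/up under the
    seed. With the default protocol this gives 54 five-volume trials:
    27 center and 9 of each direction.
    """
    if protocol.n_localizer % protocol.trial_len != 0:
        raise ValueError(
            f"n_localizer={protocol.n_localizer} is not tileable by "
            f"trial_len={protocol.trial_len}"
        )
    n_trials = protocol.n_localizer // protocol.trial_len
    n_directional = n_trials // 2
    rng = np.random.default_rng(seed)

    base, extra = divmod(n_directional, len(COMMAND_DIRECTIONS))
    labels = [d for d in COMMAND_DIRECTIONS for _ in range(base)]
    if extra:
        picks = rng.choice(len(COMMAND_DIRECTIONS), size=extra, replace=False)
        labels += [COMMAND_DIRECTIONS[int(i)] for i in picks]
    directional = [labels[i] for i in rng.permutation(len(labels))]

    trials: list[Trial] = []
    di = 0
    for k in range(n_trials):
        if k % 2 == 0:
            d = Direction.CENTER
        else:
            d = directional[di]
            di += 1
        trials.append(Trial(d, k * protocol.trial_len, protocol.trial_len))
    return CueSchedule(tuple(trials))


@dataclass(frozen=True)
class Hrf:
    """Hemodynamic impulse response sampled at TR resolution.

    ``kernel[0]`` corresponds to stimulus onset; ``lag_volumes`` is the
    kernel's peak index, usable as a labeling delay.
    """

    kernel: np.ndarray
    lag_volumes: int

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 1 or k.size == 0 or not np.all(np.isfinite(k)):
            raise ValueError("kernel must be a finite 1-D array")
        if not k.sum() > 0:
            raise ValueError("kernel must integrate to a positive value")
        object.__setattr__(self, "kernel", k)

    @classmethod
    def canonical(cls, tr_seconds: float = 1.62, duration_seconds: float = 30.0) -> "Hrf":
        """Double-gamma impulse response (peak ~6 s, undershoot ~16 s),
        sampled at TR and normalized to unit peak."""
        from scipy.stats import gamma as gamma_dist

        t = np.arange(0.0, duration_seconds, tr_seconds)
        peak = gamma_dist.pdf(t, a=6.0, scale=1.0)
        undershoot = gamma_dist.pdf(t, a=16.0, scale=1.0)
        h = peak - undershoot / 6.0
        h /= h.max()
        return cls(kernel=h, lag_volumes=int(np.argmax(h)))

    @classmethod
    def pure_delay(cls, lag_volumes: int = 3) -> "Hrf":
        """Degenerate response: a unit impulse delayed by ``lag_volumes``."""
        k = np.zeros(lag_volumes + 1)
        k[lag_volumes] = 1.0
        return cls(kernel=k, lag_volumes=lag_volumes)


def _boxcars(states: Sequence[Direction], n_volumes: int) -> dict[Direction, np.ndarray]:
    box = {d: np.zeros(n_volumes) for d in ALL_DIRECTIONS}
    for v, s in enumerate(states[:n_volumes]):
        box[s][v] = 1.0
    return box


def attention_regressors(
    schedule: CueSchedule, hrf: Hrf, n_volumes: int
) -> tuple[dict[Direction, np.ndarray], np.ndarray]:
    """Predicted responses for the four attention conditions plus a drift term.

    Each direction's boxcar (1 while its trial is on) is convolved with the
    HRF kernel and truncated to ``n_volumes``; the linear ramp drift term is
    returned separately.
    """
    if schedule.n_volumes < n_volumes:
        raise ValueError("schedule does not cover the requested volume range")
    box = _boxcars(schedule.states(), n_volumes)
    regs = {
        d: np.convolve(box[d], hrf.kernel)[:n_volumes] for d in ALL_DIRECTIONS
    }
    ramp = np.linspace(0.0, 1.0, n_volumes)
    return regs, ramp


@dataclass(frozen=True)
class Phantom:
    """Digital head phantom: baseline intensities, a brain mask, and
    direction-responsive ROIs given as fractional BOLD amplitudes."""

    baseline: np.ndarray
    brain_mask: np.ndarray
    roi_amplitude: dict[Direction, np.ndarray]  # per-voxel % of baseline, >= 0

    def __post_init__(self) -> None:
        for d, amp in self.roi_amplitude.items():
            if amp.shape != self.baseline.shape:
                raise ValueError("ROI amplitude grid must match baseline shape")
            if np.any(amp < 0):
                raise ValueError("amplitudes must be nonnegative")
            if np.any((amp > 0) & ~self.brain_mask):
                raise ValueError("ROIs must lie inside the brain mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.baseline.shape

    def roi_indices(self, direction: Direction) -> np.ndarray:
        """Sorted linear indices of the voxels responsive to ``direction``."""
        return np.flatnonzero(self.roi_amplitude[direction].ravel() > 0)


def default_phantom(
    matrix: tuple[int, int, int] = (24, 24, 12),
    baseline_value: float = 1000.0,
    amplitude: float = 0.03,
) -> Phantom:
    """Ellipsoidal brain with four disjoint cuboid ROIs.

    ROI placement mirrors the contralateral organization of attention-driven
    visual cortex at toy scale: attending LEFT activates a right-hemisphere
    block and vice versa; UP maps to an inferior block; CENTER to a medial
    foveal block. Baseline is in arbitrary scanner units (~1000).
    """
    nx, ny, nz = matrix
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ellipse = (
        ((x - cx) / (0.45 * nx)) ** 2
        + ((y - cy) / (0.45 * ny)) ** 2
        + ((z - cz) / (0.45 * nz)) ** 2
    )
    brain = ellipse <= 1.0
    # smooth tissue-like intensity variation: breaks the rotational symmetry
    # a uniform ellipsoid would have (which leaves rigid registration with an
    # unidentifiable rotation) and gives the GLM realistic baseline spread
    texture = (
        1.0
        + 0.15 * np.sin(2 * np.pi * 3 * x / nx) * np.cos(2 * np.pi * 2 * y / ny)
        + 0.10 * np.sin(2 * np.pi * 2 * z / nz + 1.0)
    )
    baseline = np.where(brain, baseline_value * texture, 0.0)

    def cuboid(x0, x1, y0, y1, z0, z1) -> np.ndarray:
        amp = np.zeros(matrix)
        amp[x0:x1, y0:y1, z0:z1] = amplitude
        amp[~brain] = 0.0
        return amp

    qx, qz = nx // 4, nz // 4
    mx, my = nx // 2, ny // 2
    rois = {
        # contralateral: LEFT attention -> right hemisphere (high x), etc.
        Direction.LEFT: cuboid(nx - qx - 4, nx - qx, my - 2, my + 2, qz + 1, qz + 4),
        Direction.RIGHT: cuboid(qx, qx + 4, my - 2, my + 2, qz + 1, qz + 4),
        Direction.UP: cuboid(mx - 2, mx + 2, my - 2, my + 2, 1, 4),
        Direction.CENTER: cuboid(mx - 2, mx + 2, my - 2, my + 2, nz - 4, nz - 1),
    }
    return Phantom(baseline=baseline, brain_mask=brain, roi_amplitude=rois)


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic corruption of the ideal BOLD signal, fully seeded.

    ``white_sd`` is additive Gaussian noise (scanner units); drift is a
    per-voxel slow random walk (step sd ``drift_walk_sd``) plus a linear
    trend with per-voxel slope drawn from N(0, ``drift_linear_sd``) over the
    run; ``motion`` optionally supplies one rigid transform per volume.
    """

    white_sd: float = 0.0
    drift_walk_sd: float = 0.0
    drift_linear_sd: float = 0.0
    motion: Sequence[RigidTransform] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.drift_walk_sd < 0 or self.drift_linear_sd < 0:
            raise ValueError("noise scales must be nonnegative")


def default_noise(seed: int = 0) -> NoiseModel:
    """Default session noise: SNR and drift chosen so attention effects are
    clearly decodable but selection and detrending are genuinely exercised."""
    return NoiseModel(white_sd=8.0, drift_walk_sd=0.8, drift_linear_sd=15.0, seed=seed)


@dataclass
class GroundTruth:
    """Per-volume true attention state and true motion parameters."""

    states: list[Direction]
    transforms: list[RigidTransform]


class OnlineSynthesizer:
    """Volume-by-volume session synthesis driven by an attention state fed
    in at each TR (supports closed-loop control, where future states depend
    on decoded output). Noise processes are continuous across the whole run
    and fully determined by the noise seed."""

    def __init__(
        self,
        protocol: ScanProtocol,
        phantom: Phantom,
        hrf: Hrf,
        noise: NoiseModel,
    ):
        if phantom.shape != tuple(protocol.matrix):
            raise ValueError("phantom grid does not match protocol matrix")
        if noise.motion is not None and len(noise.motion) != protocol.n_total:
            raise ValueError("motion trace length must equal the total volume count")
        self.protocol = protocol
        self.phantom = phantom
        self.hrf = hrf
        self.noise = noise
        self.states: list[Direction] = []
        self._rng = np.random.default_rng(noise.seed)
        n_vox = int(np.prod(phantom.shape))
        self._slope = (
            self._rng.normal(0.0, noise.drift_linear_sd, n_vox)
            if noise.drift_linear_sd > 0
            else np.zeros(n_vox)
        )
        self._walk = np.zeros(n_vox)
        self._baseline = phantom.baseline.ravel()
        self._in_brain = phantom.brain_mask.ravel()
        self._amps = {d: phantom.roi_amplitude[d].ravel() for d in ALL_DIRECTIONS}

    @property
    def volume_index(self) -> int:
        return len(self.states)

    def next_volume(self, state: Direction) -> np.ndarray:
        """Synthesize the next volume given the subject's attention state."""
        v = self.volume_index
        if v >= self.protocol.n_total:
            raise ValueError("session is complete")
        self.states.append(state)
        noise = self.noise
        n_vox = self._baseline.size
        signal = self._baseline.copy()
        kernel = self.hrf.kernel
        lo = max(0, v - kernel.size + 1)
        for u in range(lo, v + 1):  # causal HRF convolution of state history
            a = self._amps[self.states[u]]
            ku = kernel[v - u]
            if ku != 0.0 and a.any():
                signal = signal + self._baseline * a * ku
        if noise.drift_walk_sd > 0:
            self._walk = self._walk + self._rng.normal(0.0, noise.drift_walk_sd, n_vox)
            signal = signal + np.where(self._in_brain, self._walk, 0.0)
        if noise.drift_linear_sd > 0:
            frac = v / max(self.protocol.n_total - 1, 1)
            signal = signal + np.where(self._in_brain, self._slope * frac, 0.0)
        if noise.white_sd > 0:
            signal = signal + self._rng.normal(0.0, noise.white_sd, n_vox)
        vol = signal.reshape(self.phantom.shape)
        if noise.motion is not None:
            t = noise.motion[v]
            if not t.is_identity():
                # head motion moves the brain: sample the ideal volume at
                # the inverse-transformed grid
                vol = apply_rigid(vol, t.inverse(), self.protocol.voxel_mm)
        return vol

    def true_transform(self, v: int) -> RigidTransform:
        if self.noise.motion is not None:
            return self.noise.motion[v]
        return RigidTransform.identity()


def synthesize_session(
    protocol: ScanProtocol,
    schedule: CueSchedule,
    control_script: Sequence[Direction],
    phantom: Phantom,
    hrf: Hrf,
    noise: NoiseModel,
) -> tuple[Iterator[np.ndarray], GroundTruth]:
    """Stream a full synthetic session (localizer + control) volume by volume.

    Each voxel's value is ``baseline * (1 + amplitude * drive)`` where the
    drive is the voxel's direction indicator convolved with the HRF, plus
    drift and white noise; the volume is then resampled under the true
    motion transform if one is given. Returns the volume iterator and the
    ground-truth record (true states and transforms per volume).
    """
    if len(control_script) != protocol.n_control:
        raise ValueError(
            f"control_script has {len(control_script)} states, "
            f"expected {protocol.n_control}"
        )
    if schedule.n_volumes != protocol.n_localizer:
        raise ValueError("schedule does not tile the localizer phase")
    states = schedule.states() + list(control_script)
    synth = OnlineSynthesizer(protocol, phantom, hrf, noise)
    transforms = [synth.true_transform(v) for v in range(protocol.n_total)]
    truth = GroundTruth(states=states, transforms=transforms)

    def stream() -> Iterator[np.ndarray]:
        for s in states:
            yield synth.next_volume(s)

    return stream(), truth


def session_array(
    protocol: ScanProtocol,
    schedule: CueSchedule,
    control_script: Sequence[Direction],
    phantom: Phantom,
    hrf: Hrf,
    noise: NoiseModel,
) -> tuple[np.ndarray, GroundTruth]:
    """Materialize a full session as a (x, y, z, t) array. Convenience for
    batch analyses and I/O; the streaming form is :func:`synthesize_session`."""
    stream, truth = synthesize_session(
        protocol, schedule, control_script, phantom, hrf, noise
    )
    vols = np.stack(list(stream), axis=-1)
    return vols, truth
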