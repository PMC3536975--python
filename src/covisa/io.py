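"""File formats and configuration.

Sessions are 4-D NIfTI (RAS+ affine built from the voxel size; internal
voxel indexing is 0-based with axes x, y, z fastest to slowest). Ground
truth, cue events and session logs are tab-separated text; configuration
is a strict YAML file whose sections mirror the pipeline's config objects.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np
import yaml

from covisa.classifier import SvmConfig
from covisa.detrend import DetrendConfig
from covisa.motion import RegistrationConfig, RigidTransform
from covisa.simulate import (
    CueSchedule,
    Direction,
    GroundTruth,
    ScanProtocol,
    Trial,
)


def _affine(voxel_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(voxel_mm) + [1.0])
    return aff


def write_session_nifti(
    path, volumes: np.ndarray, protocol: ScanProtocol
) -> None:
    """Write a (x, y, z, t) session as 4-D NIfTI with TR in the header."""
    img = nib.Nifti1Image(np.asarray(volumes, dtype=np.float32), _affine(protocol.voxel_mm))
    img.header.set_zooms(tuple(protocol.voxel_mm) + (protocol.tr_seconds,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_volume_nifti(path, volume: np.ndarray, voxel_mm=(1.0, 1.0, 1.0)) -> None:
    """Write a single 3-D volume (t-map, mask) as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), _affine(voxel_mm)), str(path))


def read_volume_stream(
    source, protocol: ScanProtocol
) -> Iterator[tuple[int, float, np.ndarray]]:
    """Yield (index, timestamp, volume) in acquisition order.

    ``source`` is a 4-D NIfTI path or an iterable of 3-D arrays. The
    volume count and grid must match the protocol.
    """
    if isinstance(source, (str, Path)):
        img = nib.load(str(source))
        data = np.asarray(img.dataobj)
        if data.ndim != 4:
            raise ValueError(f"expected a 4-D NIfTI, got shape {data.shape}")
        if data.shape[:3] != tuple(protocol.matrix):
            raise ValueError(
                f"grid mismatch: file {data.shape[:3]}, protocol {tuple(protocol.matrix)}"
            )
        if data.shape[3] != protocol.n_total:
            raise ValueError(
                f"volume count mismatch: expected {protocol.n_total}, "
                f"found {data.shape[3]}"
            )
        vols = (data[..., v] for v in range(data.shape[3]))
    else:
        vols = iter(source)
    count = 0
    for v, vol in enumerate(vols):
        vol = np.asarray(vol, dtype=float)
        if vol.shape != tuple(protocol.matrix):
            raise ValueError(
                f"grid mismatch at volume {v}: {vol.shape} vs {tuple(protocol.matrix)}"
            )
        count += 1
        yield v, v * protocol.tr_seconds, vol
    if count != protocol.n_total:
        raise ValueError(
            f"volume count mismatch: expected {protocol.n_total}, found {count}"
        )


def write_events(path, schedule: CueSchedule, tr_seconds: float) -> None:
    """Cue schedule as a tab-separated events file (onset, duration, label)
    in seconds."""
    with open(path, "w") as fh:
        fh.write("onset\tduration\tlabel\n")
        for t in schedule.trials:
            fh.write(
                f"{t.start_volume * tr_seconds:.2f}\t"
                f"{t.length_volumes * tr_seconds:.2f}\t{t.direction.value}\n"
            )


def read_events(path, tr_seconds: float) -> CueSchedule:
    trials = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            onset, duration, label = line.rstrip("\n").split("\t")
            trials.append(
                Trial(
                    Direction(label),
                    int(round(float(onset) / tr_seconds)),
                    int(round(float(duration) / tr_seconds)),
                )
            )
    return CueSchedule(tuple(trials))


def write_ground_truth(path, truth: GroundTruth) -> None:
    """Sidecar table: volume index, true state, true transform parameters."""
    with open(path, "w") as fh:
        fh.write("volume\tstate\trx\try\trz\ttx\tty\ttz\n")
        for v, (s, t) in enumerate(zip(truth.states, truth.transforms)):
            p = "\t".join(f"{x:.9g}" for x in t.params)
            fh.write(f"{v}\t{s.value}\t{p}\n")


def read_ground_truth(path) -> GroundTruth:
    states, transforms = [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            states.append(Direction(parts[1]))
            p = np.array([float(x) for x in parts[2:8]])
            transforms.append(RigidTransform.from_params(p))
    return GroundTruth(states=states, transforms=transforms)


def write_mask_indices(path, mask) -> None:
    """Plain-text linear index list of the feature mask."""
    with open(path, "w") as fh:
        fh.write("# linear voxel indices, grid shape "
                 f"{'x'.join(str(s) for s in mask.shape)}\n")
        for i, lab in zip(mask.voxel_indices, mask.cluster_labels):
            fh.write(f"{int(i)}\t{int(lab)}\n")


def write_session_log(path, log) -> None:
    """Tab-separated per-volume log plus target-arrival summary block."""
    with open(path, "w") as fh:
        fh.write("volume\tdecoded\tcommand\trefractory\tx\ty\theading\n")
        for r in log.records:
            cmd = r.command.value if r.command else "-"
            fh.write(
                f"{r.volume}\t{r.decoded.value}\t{cmd}\t{int(r.refractory)}\t"
                f"{r.pose.x:.2f}\t{r.pose.y:.2f}\t{r.pose.heading:.2f}\n"
            )
        fh.write("\n# target arrivals (cumulative seconds, cumulative movements)\n")
        for line in log.summary_lines():
            fh.write("# " + line + "\n")
        fh.write(f"# commands_issued\t{log.commands_issued}\n")
        fh.write(f"# mask_size\t{log.mask_size}\n")
        if log.localizer_accuracy is not None:
            fh.write(f"# localizer_accuracy\t{log.localizer_accuracy:.4f}\n")


def plot_path(log, arena, path) -> None:
    """Fig-style floor map of the robot trajectory with target rectangles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(5, 6))
    ax.add_patch(Rectangle((0, 0), arena.width, arena.depth, fill=False, lw=1.5))
    for t in arena.targets:
        ax.add_patch(
            Rectangle(
                (t.x_min, t.y_min), t.x_max - t.x_min, t.y_max - t.y_min,
                alpha=0.3, color="tab:green",
            )
        )
        cx, cy = t.center
        ax.text(cx, cy, str(t.label), ha="center", va="center")
    xs = [r.pose.x for r in log.records]
    ys = [r.pose.y for r in log.records]
    ax.plot(xs, ys, "-", lw=1, color="tab:blue")
    ax.plot(xs[0], ys[0], "o", color="tab:red")
    ax.set_xlim(-20, arena.width + 20)
    ax.set_ylim(-20, arena.depth + 20)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


# --------------------------------------------------------------------------
# configuration

_SECTION_TYPES = {
    "protocol": ScanProtocol,
    "svm": SvmConfig,
    "detrend": DetrendConfig,
    "registration": RegistrationConfig,
}

_TOP_LEVEL_SCALARS = {
    "seed": int,
    "out_dir": str,
    "top_k_per_map": int,
    "min_cluster": int,
    "connectivity": int,
    "motion_correct": bool,
    "decoder": str,
    "white_sd": float,
    "drift_walk_sd": float,
    "drift_linear_sd": float,
    "jitter_cm": float,
    "jitter_deg": float,
    "toy_grid": bool,
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated, round-trippable run configuration.

    Unknown sections or keys are rejected; defaults mirror the published
    parameters (TR 1.62 s, lambda 200, C 1, k 500, min cluster 5, sigma 1,
    50 iterations, 50 cm forward, 30 degree turns, 4-volume washout).
    """

    protocol: ScanProtocol = dataclasses.field(default_factory=ScanProtocol)
    svm: SvmConfig = dataclasses.field(default_factory=SvmConfig)
    detrend: DetrendConfig = dataclasses.field(default_factory=DetrendConfig)
    registration: RegistrationConfig = dataclasses.field(
        default_factory=RegistrationConfig
    )
    seed: int = 0
    out_dir: str = "covisa_out"
    top_k_per_map: int = 500
    min_cluster: int = 5
    connectivity: int = 6
    motion_correct: bool = False
    decoder: str = "svm"
    white_sd: float = 8.0
    drift_walk_sd: float = 0.8
    drift_linear_sd: float = 15.0
    jitter_cm: float = 0.0
    jitter_deg: float = 0.0
    toy_grid: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        kwargs = {}
        for key, value in raw.items():
            if key in _SECTION_TYPES:
                typ = _SECTION_TYPES[key]
                valid = {f.name for f in dataclasses.fields(typ)}
                unknown = set(value) - valid
                if unknown:
                    raise ValueError(
                        f"unknown keys in section '{key}': {sorted(unknown)}"
                    )
                coerced = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in value.items()
                }
                kwargs[key] = typ(**coerced)
            elif key in _TOP_LEVEL_SCALARS:
                kwargs[key] = _TOP_LEVEL_SCALARS[key](value)
            else:
                raise ValueError(f"unknown config key: '{key}'")
        return cls(**kwargs)

    def to_file(self, path) -> None:
        out: dict = {}
        for name, typ in _SECTION_TYPES.items():
            section = dataclasses.asdict(getattr(self, name))
            section = {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in section.items()
            }
            out[name] = section
        for key in _TOP_LEVEL_SCALARS:
            out[key] = getattr(self, key)
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=True)

    def effective_protocol(self) -> ScanProtocol:
        return self.protocol.toy() if self.toy_grid else self.protocol
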