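"""Closed-loop robot control: refractory state machine, arena kinematics,
target sequencing, and the full localizer-then-control session driver.

A decoded RIGHT/LEFT/UP volume issues a turn-right / turn-left / forward
command; the following volume carries the movement and the next four
volumes (6.48 s) are a washout with the video feed off, so no command can
be acted on during that 5-volume refractory window. CENTER never issues a
command. Forward moves the robot 50 cm; turns are 30 degrees; a forward
move that would cross a wall reverts to the previous pose.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from covisa.detrend import DetrendConfig
from covisa.classifier import SvmConfig, classify
from covisa.simulate import (
    Direction,
    Hrf,
    NoiseModel,
    Phantom,
    ScanProtocol,
    build_cue_schedule,
    default_phantom,
)

REFRACTORY_VOLUMES = 5  # 1 movement volume + 4 washout volumes
WASHOUT_VOLUMES = 4
BOLD_RISE_VOLUMES = 5  # sustained attention needed before a decodable signal
FORWARD_CM = 50.0
TURN_DEG = 30.0


def timing_facts(protocol: ScanProtocol) -> dict[str, float]:
    """Session timing quantities implied by the protocol and the
    refractory/rise structure (all in seconds except counts)."""
    tr = protocol.tr_seconds
    min_volumes = BOLD_RISE_VOLUMES + 1 + WASHOUT_VOLUMES  # rise + move + washout
    return {
        "trial_seconds": protocol.trial_len * tr,
        "washout_seconds": WASHOUT_VOLUMES * tr,
        "min_intercommand_seconds": min_volumes * tr,
        "control_phase_seconds": protocol.n_control * tr,
        "max_commands": float(protocol.n_control // min_volumes),
        "total_volumes": float(protocol.n_total),
    }


class Command(str, enum.Enum):
    FORWARD = "forward"
    TURN_RIGHT = "turn_right"
    TURN_LEFT = "turn_left"


COMMAND_FOR_LABEL = {
    Direction.UP: Command.FORWARD,
    Direction.RIGHT: Command.TURN_RIGHT,
    Direction.LEFT: Command.TURN_LEFT,
}


@dataclass
class ControlState:
    """Refractory bookkeeping for the command state machine."""

    refractory_remaining: int = 0
    commands_issued: int = 0
    volume_index: int = 0

    @property
    def video_on(self) -> bool:
        # video is off exactly during the 4 washout volumes (the first
        # refractory volume carries the movement itself)
        return not (0 < self.refractory_remaining <= WASHOUT_VOLUMES)


def step(state: ControlState, label: Direction) -> tuple[Command | None, ControlState]:
    """Advance the state machine by one classified volume.

    Inside the refractory window classifications are logged but suppressed;
    otherwise RIGHT/LEFT/UP emit their command and open a new 5-volume
    refractory window. CENTER never acts.
    """
    new = replace(state)
    new.volume_index = state.volume_index + 1
    if state.refractory_remaining > 0:
        new.refractory_remaining = state.refractory_remaining - 1
        return None, new
    if label in COMMAND_FOR_LABEL:
        new.refractory_remaining = REFRACTORY_VOLUMES
        new.commands_issued = state.commands_issued + 1
        return COMMAND_FOR_LABEL[label], new
    return None, new


@dataclass(frozen=True)
class RobotPose:
    """Planar pose: position in cm, heading in degrees CCW (0 = +x)."""

    x: float
    y: float
    heading: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "heading", self.heading % 360.0)


@dataclass(frozen=True)
class TargetZone:
    """Closed axis-aligned rectangle on the floor (cm)."""

    label: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    @property
    def center(self) -> tuple[float, float]:
        return (self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0


@dataclass(frozen=True)
class Arena:
    """Rectangular room with four floor targets; the run starts at target 4."""

    width: float
    depth: float
    targets: tuple[TargetZone, TargetZone, TargetZone, TargetZone]
    start_pose: RobotPose

    def __post_init__(self) -> None:
        for t in self.targets:
            if not (
                0 <= t.x_min <= t.x_max <= self.width
                and 0 <= t.y_min <= t.y_max <= self.depth
            ):
                raise ValueError(f"target {t.label} lies outside the arena")

    def inside(self, x: float, y: float) -> bool:
        return 0 <= x <= self.width and 0 <= y <= self.depth


def default_arena() -> Arena:
    """4 x 5 m room, 25 x 50 cm targets at the corners of an inner loop,
    robot starting at target four."""
    def zone(label: int, cx: float, cy: float) -> TargetZone:
        return TargetZone(label, cx - 12.5, cy - 25.0, cx + 12.5, cy + 25.0)

    targets = (
        zone(1, 100.0, 400.0),
        zone(2, 300.0, 400.0),
        zone(3, 300.0, 100.0),
        zone(4, 100.0, 100.0),
    )
    return Arena(
        width=400.0,
        depth=500.0,
        targets=targets,
        start_pose=RobotPose(100.0, 100.0, 90.0),
    )


def execute(
    pose: RobotPose,
    command: Command,
    arena: Arena,
    jitter_cm: float = 0.0,
    jitter_deg: float = 0.0,
    rng: np.random.Generator | None = None,
) -> RobotPose:
    """Apply a command to the pose with optional movement jitter.

    A forward move whose endpoint (or path) would leave the room reverts
    to the pre-command pose, emulating the manual reset after a wall hit.
    """
    dist, dturn = FORWARD_CM, 0.0
    if rng is not None and (jitter_cm > 0 or jitter_deg > 0):
        dist += rng.normal(0.0, jitter_cm)
        dturn = rng.normal(0.0, jitter_deg)
    if command is Command.TURN_RIGHT:
        return RobotPose(pose.x, pose.y, pose.heading - TURN_DEG + dturn)
    if command is Command.TURN_LEFT:
        return RobotPose(pose.x, pose.y, pose.heading + TURN_DEG + dturn)
    theta = math.radians(pose.heading)
    nx = pose.x + dist * math.cos(theta)
    ny = pose.y + dist * math.sin(theta)
    if not arena.inside(nx, ny):
        return pose  # wall: moved back to the previous position/orientation
    return RobotPose(nx, ny, pose.heading)


@dataclass
class TargetProgress:
    """Sequential target tracking; cycles 1 -> 2 -> 3 -> 4 -> 1 -> ..."""

    next_index: int = 0  # index into arena.targets
    reached: list[tuple[int, float, int]] = field(default_factory=list)
    # entries: (running target number, cumulative seconds, cumulative moves)

    @property
    def targets_reached(self) -> int:
        return len(self.reached)


def check_targets(
    pose: RobotPose,
    arena: Arena,
    progress: TargetProgress,
    elapsed_seconds: float,
    movements: int,
) -> TargetProgress:
    """Credit the next expected target if the robot's center is inside it."""
    zone = arena.targets[progress.next_index]
    if zone.contains(pose.x, pose.y):
        progress.reached.append(
            (progress.targets_reached + 1, elapsed_seconds, movements)
        )
        progress.next_index = (progress.next_index + 1) % len(arena.targets)
    return progress


@dataclass
class VolumeRecord:
    volume: int
    decoded: Direction
    command: Command | None
    refractory: bool
    pose: RobotPose


@dataclass
class SessionLog:
    """Per-volume control-phase records plus target-arrival summary."""

    records: list[VolumeRecord] = field(default_factory=list)
    target_times: list[tuple[int, float, int]] = field(default_factory=list)
    commands_issued: int = 0
    mask_size: int = 0
    localizer_accuracy: float | None = None

    def summary_lines(self) -> list[str]:
        """Cumulative time (s) and movement count per target, in sequence."""
        out = ["target\tcumulative_seconds\tcumulative_movements"]
        for n, secs, moves in self.target_times:
            out.append(f"{n}\t{secs:.1f}\t{moves}")
        return out


class PlannerUser:
    """Scripted subject: attends toward whichever command reduces the
    distance to the next target, returns to CENTER during washout, and
    sustains attention long enough for the BOLD response to rise before a
    volume becomes decodable."""

    def __init__(self, arena: Arena, rise_volumes: int = BOLD_RISE_VOLUMES):
        self.arena = arena
        self.rise_volumes = rise_volumes
        self._attending: Direction = Direction.CENTER
        self._held = 0
        # the localizer ends on a directional trial whose BOLD response is
        # still high when control starts; rest until it washes out
        self._initial_rest = WASHOUT_VOLUMES

    def intended_direction(self, pose: RobotPose, target: TargetZone) -> Direction:
        tx, ty = target.center
        bearing = math.degrees(math.atan2(ty - pose.y, tx - pose.x))
        delta = (bearing - pose.heading + 180.0) % 360.0 - 180.0
        dist = math.hypot(tx - pose.x, ty - pose.y)
        if abs(delta) <= TURN_DEG / 2.0:
            # forward only if it actually closes distance (avoid overshoot)
            theta = math.radians(pose.heading)
            nx, ny = pose.x + FORWARD_CM * math.cos(theta), pose.y + FORWARD_CM * math.sin(theta)
            if math.hypot(tx - nx, ty - ny) < dist and self.arena.inside(nx, ny):
                return Direction.UP
            # already as close as a forward step allows: nudge heading
            return Direction.LEFT if delta > 0 else Direction.RIGHT
        return Direction.LEFT if delta > 0 else Direction.RIGHT

    def attention_state(
        self, pose: RobotPose, progress: TargetProgress, in_refractory: bool
    ) -> tuple[Direction, Direction]:
        """Return (true attention state, decodable label).

        The decodable label stays CENTER until attention has been sustained
        for ``rise_volumes`` volumes, reproducing the hemodynamic rise that
        makes the minimum spacing between commands 10 TRs."""
        if in_refractory or self._initial_rest > 0:
            self._initial_rest = max(0, self._initial_rest - 1)
            self._attending = Direction.CENTER
            self._held = 0
            return Direction.CENTER, Direction.CENTER
        want = self.intended_direction(pose, self.arena.targets[progress.next_index])
        if want == self._attending:
            self._held += 1
        else:
            self._attending = want
            self._held = 1
        decodable = want if self._held >= self.rise_volumes else Direction.CENTER
        return want, decodable


def run_control_phase(
    labels_for_volume: Callable[[int, ControlState, RobotPose, TargetProgress], Direction],
    n_control: int,
    arena: Arena,
    tr_seconds: float,
    jitter_cm: float = 0.0,
    jitter_deg: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SessionLog:
    """Drive the state machine / kinematics for one control phase."""
    state = ControlState()
    pose = arena.start_pose
    progress = TargetProgress()
    log = SessionLog()
    for v in range(n_control):
        label = labels_for_volume(v, state, pose, progress)
        refractory = state.refractory_remaining > 0
        command, state = step(state, label)
        if command is not None:
            pose = execute(pose, command, arena, jitter_cm, jitter_deg, rng)
            progress = check_targets(
                pose, arena, progress, (v + 1) * tr_seconds, state.commands_issued
            )
        log.records.append(VolumeRecord(v, label, command, refractory, pose))
    log.target_times = list(progress.reached)
    log.commands_issued = state.commands_issued
    return log


def run_closed_loop(
    protocol: ScanProtocol | None = None,
    arena: Arena | None = None,
    seed: int = 0,
    phantom: Phantom | None = None,
    hrf: Hrf | None = None,
    noise: NoiseModel | None = None,
    svm_config: SvmConfig = SvmConfig(),
    detrend_config: DetrendConfig = DetrendConfig(),
    decoder: str = "svm",
    top_k_per_map: int = 500,
    min_cluster: int = 5,
    motion_correct: bool = False,
    jitter_cm: float = 0.0,
    jitter_deg: float = 0.0,
) -> SessionLog:
    """Full session: simulate, train on the localizer, decode the control
    phase volume by volume, and drive the robot.

    ``decoder='truth'`` bypasses the SVM and feeds the ground-truth
    decodable labels straight to the state machine (perfect-decoder mode,
    used to validate the planner and kinematics). Deterministic given seed.
    """
    from covisa.pipeline import run_localizer  # local import to avoid cycle
    from covisa.simulate import OnlineSynthesizer, default_noise

    protocol = protocol or ScanProtocol().toy()
    arena = arena or default_arena()
    phantom = phantom or default_phantom(protocol.matrix)
    hrf = hrf or Hrf.canonical(protocol.tr_seconds)
    if noise is None:
        noise = default_noise(seed)
    rng = np.random.default_rng(seed + 1)
    schedule = build_cue_schedule(protocol, seed)
    user = PlannerUser(arena)

    # The control phase is closed-loop: the user's attention depends on the
    # robot's pose, which depends on decoded output of earlier volumes. The
    # synthesizer therefore produces volumes one TR at a time from the
    # evolving attention state, with noise processes continuous across the
    # localizer/control boundary.
    synth = OnlineSynthesizer(protocol, phantom, hrf, noise)
    loc_vols = [synth.next_volume(s) for s in schedule.states()]
    loc = run_localizer(
        loc_vols,
        schedule,
        protocol,
        hrf,
        svm_config=svm_config,
        detrend_config=detrend_config,
        top_k_per_map=top_k_per_map,
        min_cluster=min_cluster,
        motion_correct=motion_correct,
        seed=seed,
    )
    log = SessionLog()
    log.mask_size = loc.mask.size
    log.localizer_accuracy = loc.training_accuracy

    state = ControlState()
    pose = arena.start_pose
    progress = TargetProgress()
    template = loc.template

    for cv in range(protocol.n_control):
        in_refractory = state.refractory_remaining > 0
        attend, decodable = user.attention_state(pose, progress, in_refractory)
        vol = synth.next_volume(attend)
        if decoder == "truth":
            label = decodable
        else:
            if motion_correct:
                from covisa.motion import correct_volume

                vol, _ = correct_volume(
                    vol, template, seed=seed + 100_000 + cv,
                    voxel_mm=protocol.voxel_mm,
                )
            feats = loc.normalizer.process_control_volume(loc.mask.extract(vol))
            label = classify(loc.model, feats)
        command, state = step(state, label)
        if command is not None:
            pose = execute(pose, command, arena, jitter_cm, jitter_deg, rng)
            progress = check_targets(
                pose, arena, progress, (cv + 1) * protocol.tr_seconds,
                state.commands_issued,
            )
        log.records.append(VolumeRecord(cv, label, command, in_refractory, pose))

    log.target_times = list(progress.reached)
    log.commands_issued = state.commands_issued
    return log
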