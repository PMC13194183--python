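"""Geometry and trial design of the goal-directed reaching task.

The task: from a resting position, move a cursor (driven by the hand on a
joystick, or by leaning with the full body, tracked as the center-of-mass
projection) to one of two targets placed symmetrically about the midline.
On 75% of trials the cursor trajectory is rotated about the origin by a
signed angle once the effector passes a fixed radial distance, and the
participant reports whether the movement seen matched the movement made.

Coordinate conventions
----------------------
Workspace positions are in millimetres with the resting position at the
origin, +y straight ahead and +x to the right. Bearings are measured in
degrees clockwise from the +y axis, so the right target sits at a positive
bearing. A positive deviation rotates the cursor clockwise.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

DEVIATION_MAGNITUDES = (7.5, 15.0, 22.5, 30.0)
#: signed deviations allowed in the design, degrees (0 = veridical feedback)
DEVIATION_SET = (0.0,) + tuple(s * m for m in DEVIATION_MAGNITUDES for s in (1.0, -1.0))

N_CONTROL_PER_BLOCK = 24
N_PER_DEVIATION = 16
N_TRIALS_PER_BLOCK = N_CONTROL_PER_BLOCK + N_PER_DEVIATION * len(DEVIATION_MAGNITUDES)


class Effector(str, enum.Enum):
    HAND = "hand"
    FULL_BODY = "full_body"


class Task(str, enum.Enum):
    SINGLE = "single"
    DUAL = "dual"


class TargetSide(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Mode(str, enum.Enum):
    CONTROL = "control"
    CONVERGING = "converging"
    DIVERGING = "diverging"


class InvalidGeometryError(ValueError):
    """Raised when task geometry violates its physical constraints."""


class InvalidTrialError(ValueError):
    """Raised for trial parameters outside the experimental design."""


@dataclass(frozen=True)
class TaskGeometry:
    """Physical geometry of one participant's workspace.

    Parameters
    ----------
    pelvis_height_m
        Participant pelvis height in metres; the full-body range of motion
        scales with it through the platform's maximum tilt.
    max_tilt_deg
        Maximum tilt of the balance platform, degrees.
    target_angle_deg
        Targets sit at +/- this bearing from the midline.
    radius_fraction
        Targets are placed at this fraction of the range of motion.
    deviation_onset_mm
        Radial distance beyond which the cursor rotation is applied.
    sampling_rate_hz
        Sampling rate of the effector stream.
    """

    pelvis_height_m: float = 1.0
    max_tilt_deg: float = 8.5
    target_angle_deg: float = 25.0
    radius_fraction: float = 0.8
    deviation_onset_mm: float = 25.0
    sampling_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        if self.pelvis_height_m <= 0:
            raise InvalidGeometryError("pelvis_height_m must be positive")
        if not 0 < self.radius_fraction <= 1:
            raise InvalidGeometryError("radius_fraction must be in (0, 1]")
        if not 0 < self.target_angle_deg < 90:
            raise InvalidGeometryError("target_angle_deg must be in (0, 90)")
        if self.sampling_rate_hz <= 0:
            raise InvalidGeometryError("sampling_rate_hz must be positive")
        if self.deviation_onset_mm >= self.target_radius_mm:
            raise InvalidGeometryError(
                "deviation_onset_mm must be smaller than the target radial "
                f"distance ({self.target_radius_mm:.1f} mm)"
            )

    @property
    def target_radius_mm(self) -> float:
        return self.radius_fraction * range_of_motion(self) * 1000.0


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial of the action-monitoring block."""

    trial_index: int
    effector: Effector
    task: Task
    target_side: TargetSide
    deviation_deg: float
    mode: Mode = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mode", classify_mode(self.target_side, self.deviation_deg)
        )


@dataclass(frozen=True)
class SubBlockDesign:
    """Ordered, balanced set of 88 trials for one effector x task cell."""

    trials: tuple[TrialSpec, ...]
    seed: int
    effector: Effector
    task: Task


def range_of_motion(geometry: TaskGeometry) -> float:
    """Range of motion in metres: sin(max tilt) x pelvis height.

    For the full body this is the horizontal excursion of the center of
    mass at the platform's maximum tilt; the joystick workspace is mapped
    onto the same cursor space.
    """
    if geometry.pelvis_height_m <= 0:
        raise InvalidGeometryError("pelvis_height_m must be positive")
    return math.sin(math.radians(geometry.max_tilt_deg)) * geometry.pelvis_height_m


def bearing_deg(x: float | np.ndarray, y: float | np.ndarray) -> float | np.ndarray:
    """Bearing in degrees clockwise from +y (straight ahead)."""
    return np.degrees(np.arctan2(x, y))


def target_bearing(geometry: TaskGeometry, side: TargetSide) -> float:
    sign = 1.0 if side == TargetSide.RIGHT else -1.0
    return sign * geometry.target_angle_deg


def target_positions(geometry: TaskGeometry) -> dict[TargetSide, np.ndarray]:
    """Target positions in mm, keyed by side; resting position is the origin."""
    r = geometry.target_radius_mm
    out = {}
    for side in (TargetSide.LEFT, TargetSide.RIGHT):
        b = math.radians(target_bearing(geometry, side))
        out[side] = np.array([r * math.sin(b), r * math.cos(b)])
    return out


def classify_mode(target_side: TargetSide | str, deviation_deg: float) -> Mode:
    """Classify a trial as control / converging / diverging.

    Converging: the rotation pushes the cursor toward the target side, so
    the compensatory movement is toward the midline. Diverging: the
    rotation conflicts with the target side and compensation is toward
    the periphery. Clockwise rotations are positive, the right target is
    on the positive side, hence converging iff sign(deviation) matches
    the target side.
    """
    if abs(deviation_deg) not in (0.0,) + DEVIATION_MAGNITUDES:
        raise InvalidTrialError(f"deviation {deviation_deg} not in the design")
    if deviation_deg == 0:
        return Mode.CONTROL
    side = TargetSide(target_side)
    toward_right = deviation_deg > 0
    if (side == TargetSide.RIGHT) == toward_right:
        return Mode.CONVERGING
    return Mode.DIVERGING


def apply_deviation(
    point: np.ndarray, deviation_deg: float, geometry: TaskGeometry
) -> np.ndarray:
    """Map an effector position to the displayed cursor position.

    Inside the onset radius the cursor is veridical; beyond it the point
    is rotated about the origin by the signed deviation (clockwise
    positive), which preserves radial distance.
    """
    point = np.asarray(point, dtype=float)
    r = float(np.hypot(point[0], point[1]))
    if r <= geometry.deviation_onset_mm or deviation_deg == 0:
        return point.copy()
    a = math.radians(deviation_deg)
    c, s = math.cos(a), math.sin(a)
    # clockwise rotation: bearing increases by `deviation_deg`
    return np.array([point[0] * c + point[1] * s, -point[0] * s + point[1] * c])


def com_projection(
    roll_deg: float | np.ndarray,
    pitch_deg: float | np.ndarray,
    pelvis_height_m: float,
) -> np.ndarray:
    """Planar center-of-mass projection from trunk tilt angles.

    Frontal (x) coordinate = pelvis height x sin(roll); sagittal (y)
    coordinate = pelvis height x sin(pitch). Returned in metres.
    """
    return np.asarray(
        [
            pelvis_height_m * np.sin(np.radians(roll_deg)),
            pelvis_height_m * np.sin(np.radians(pitch_deg)),
        ]
    )


def build_subblock(
    effector: Effector | str,
    task: Task | str,
    geometry: TaskGeometry,  # noqa: ARG001 - kept for interface symmetry
    seed: int,
) -> SubBlockDesign:
    """Build one randomized 88-trial sub-block.

    24 control trials plus 16 per deviation magnitude, each magnitude
    balanced 4/4/4/4 over sign x target side; control trials split 12/12
    over targets. The order is a seeded uniform shuffle.
    """
    effector = Effector(effector)
    task = Task(task)
    cells: list[tuple[TargetSide, float]] = []
    for side in (TargetSide.LEFT, TargetSide.RIGHT):
        cells.extend([(side, 0.0)] * (N_CONTROL_PER_BLOCK // 2))
        for mag in DEVIATION_MAGNITUDES:
            for sign in (1.0, -1.0):
                cells.extend([(side, sign * mag)] * (N_PER_DEVIATION // 4))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    trials = tuple(
        TrialSpec(
            trial_index=i,
            effector=effector,
            task=task,
            target_side=cells[j][0],
            deviation_deg=cells[j][1],
        )
        for i, j in enumerate(order)
    )
    return SubBlockDesign(trials=trials, seed=seed, effector=effector, task=task)
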