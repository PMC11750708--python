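"""Finger-position to quadcopter velocity control and ring courses.

The four finger DOF map to a velocity-control paradigm: thumb
flexion/extension drives forward/backward translation, thumb
abduction/adduction left/right, index-middle flexion/extension elevation,
and ring-little flexion/extension yaw.  Displacements from neutral
(``s = 2u - 1``) are multiplied by per-DOF gains (0.6, 0.8, 0.4, 0.6) and
scaled to the velocity caps of +-10 m/s (linear) and +-90 deg/s (yaw).
A low-amplitude "gravity" biases each finger back to neutral whenever it
is within 10% of the range of motion of neutral, so fingers rest still
between deliberate movements.

The quadcopter itself is a first-order kinematic body: commands are
velocities that integrate directly (the control semantics are
velocity-level; aerodynamics are out of scope).  Courses are sequences of
rings; crossing detection intersects each 50-ms flight segment with the
ring's disc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .population import BIN_WIDTH_S
from .tasks import FingerState

__all__ = [
    "ControlMapping",
    "QuadPose",
    "Ring",
    "apply_neutral_gravity",
    "fingers_to_command",
    "step_quadcopter",
    "ring_crossing",
    "obstacle_course",
    "random_ring_course",
    "run_course",
    "FlightSummary",
]


@dataclass(frozen=True)
class ControlMapping:
    gains: tuple[float, float, float, float] = (0.6, 0.8, 0.4, 0.6)
    max_linear_speed: float = 10.0    # m/s
    max_yaw_rate: float = 90.0        # deg/s
    neutral_zone: float = 0.10        # fraction of ROM around neutral
    gravity_amplitude: float = 0.05   # ROM-units/s toward neutral
    # sign conventions are configurable; defaults: flexion -> forward,
    # abduction -> right, index-middle flexion -> up, ring-little flexion ->
    # rightward (positive) yaw
    signs: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.gains):
            raise ValueError("gains must be nonnegative")
        if not 0.0 < self.neutral_zone < 0.5:
            raise ValueError("neutral_zone must be in (0, 0.5)")
        if self.gravity_amplitude * BIN_WIDTH_S >= self.neutral_zone:
            raise ValueError(
                "gravity_amplitude * bin width must stay below the neutral zone"
            )


@dataclass
class QuadPose:
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))  # m, world
    yaw: float = 0.0                                                   # deg, [0, 360)
    clock: float = 0.0                                                 # s

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.yaw = float(self.yaw) % 360.0


@dataclass(frozen=True)
class Ring:
    center: np.ndarray
    normal: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("ring normal must be nonzero")
        object.__setattr__(self, "normal", n / nn)
        if self.radius <= 0:
            raise ValueError("ring radius must be > 0")


def apply_neutral_gravity(
    position_u: np.ndarray, decoded_velocity: np.ndarray, mapping: ControlMapping
) -> np.ndarray:
    """Bias finger velocities toward neutral inside the neutral zone.

    When a finger is within ``neutral_zone`` of u = 0.5 (but not exactly at
    it), a constant ``gravity_amplitude`` toward neutral is added to its
    decoded velocity; outside the zone the velocity is unchanged.
    """
    u = np.asarray(position_u, dtype=float)
    v = np.asarray(decoded_velocity, dtype=float).copy()
    offset = u - 0.5
    in_zone = (np.abs(offset) < mapping.neutral_zone) & (offset != 0.0)
    v = np.where(in_zone, v - np.sign(offset) * mapping.gravity_amplitude, v)
    return v


def fingers_to_command(state: FingerState, mapping: ControlMapping):
    """(v_forward, v_right, v_up, yaw_rate) from 4-DOF finger positions.

    Displacement s = 2u - 1 per DOF, times the per-DOF gain, times the
    relevant cap; magnitudes are clamped to the caps.  Odd-symmetric:
    negating all displacements negates every command.
    """
    if len(state.positions) != 4:
        raise ValueError("quadcopter control requires a 4-DOF finger state")
    s = state.display * np.asarray(mapping.signs)
    g = np.asarray(mapping.gains)
    lin = np.clip(
        g[:3] * s[:3] * mapping.max_linear_speed,
        -mapping.max_linear_speed,
        mapping.max_linear_speed,
    )
    yaw_rate = float(
        np.clip(
            g[3] * s[3] * mapping.max_yaw_rate,
            -mapping.max_yaw_rate,
            mapping.max_yaw_rate,
        )
    )
    # axis order: thumb_flex -> forward, thumb_abd -> right, index_middle -> up
    return float(lin[0]), float(lin[1]), float(lin[2]), yaw_rate


def step_quadcopter(pose: QuadPose, command, dt: float = BIN_WIDTH_S) -> QuadPose:
    """Integrate one time step of the kinematic quadcopter.

    Yaw integrates the yaw rate; body-frame (forward, right) velocities are
    rotated into the world frame at the half-step (midpoint) yaw, which
    keeps circular arcs second-order accurate; elevation adds directly.
    World frame: x = initial forward, y = initial right, z = up.
    """
    v_fwd, v_right, v_up, yaw_rate = (float(c) for c in command)
    if not all(np.isfinite([v_fwd, v_right, v_up, yaw_rate])):
        raise ValueError("command must be finite")
    yaw_mid = np.deg2rad(pose.yaw + 0.5 * yaw_rate * dt)
    cos, sin = np.cos(yaw_mid), np.sin(yaw_mid)
    # forward axis rotated by yaw in the horizontal plane (yaw positive
    # turns forward toward the right/+y axis)
    dx = (v_fwd * cos - v_right * sin) * dt
    dy = (v_fwd * sin + v_right * cos) * dt
    dz = v_up * dt
    return QuadPose(
        position=pose.position + np.array([dx, dy, dz]),
        yaw=(pose.yaw + yaw_rate * dt) % 360.0,
        clock=pose.clock + dt,
    )


def ring_crossing(pose_before: QuadPose, pose_after: QuadPose, ring: Ring) -> bool:
    """True iff the flight segment passes through the ring's disc."""
    p0, p1 = pose_before.position, pose_after.position
    seg = p1 - p0
    if np.linalg.norm(seg) == 0.0:
        return False
    d0 = float(np.dot(p0 - ring.center, ring.normal))
    d1 = float(np.dot(p1 - ring.center, ring.normal))
    if d0 == 0.0 and d1 == 0.0:
        return False  # sliding within the plane is not a crossing
    if (d0 > 0 and d1 > 0) or (d0 < 0 and d1 < 0):
        return False
    t = d0 / (d0 - d1)
    hit = p0 + t * seg
    return float(np.linalg.norm(hit - ring.center)) <= ring.radius


# -------------------------------------------------------------------- courses


@dataclass(frozen=True)
class CourseSpec:
    kind: str                        # "obstacle" | "random_rings"
    rings: tuple[Ring, ...] = ()
    ring_timeout: float = 20.0       # s, random-ring mode
    seed: int = 0
    box: tuple[float, float, float] = (20.0, 20.0, 8.0)  # random-ring volume, m


def obstacle_course(
    ring_spacing: float = 10.0, ring_radius: float = 1.5, height: float = 2.0
) -> CourseSpec:
    """The fixed two-ring course: rings along the long court axis."""
    r1 = Ring(np.array([ring_spacing, 0.0, height]), np.array([1.0, 0.0, 0.0]), ring_radius)
    r2 = Ring(np.array([2 * ring_spacing, 0.0, height]), np.array([1.0, 0.0, 0.0]), ring_radius)
    return CourseSpec("obstacle", (r1, r2))


def random_ring_course(seed: int = 0, ring_timeout: float = 20.0) -> CourseSpec:
    return CourseSpec("random_rings", (), ring_timeout, seed)


def _random_ring(rng: np.random.Generator, box, ring_radius: float = 1.5) -> Ring:
    bx, by, bz = box
    center = np.array(
        [rng.uniform(-bx, bx), rng.uniform(-by, by), rng.uniform(1.0, bz)]
    )
    normal = rng.standard_normal(3)
    return Ring(center, normal, ring_radius)


@dataclass
class FlightSummary:
    total_time: float
    rings_crossed: int
    rings_per_min: float
    timeouts: int
    events: list            # (time, "ring" | "timeout")
    poses: list


def run_course(
    course_spec: CourseSpec,
    controller: Callable[[QuadPose, Ring | None, float], FingerState],
    mapping: ControlMapping | None = None,
    max_time: float = 120.0,
) -> FlightSummary:
    """Fly a course with a finger controller at 50-ms control steps.

    ``controller(pose, active_ring, t)`` returns the 4-DOF finger state for
    the step; it is mapped through :func:`fingers_to_command`.  In obstacle
    mode the rings are visited in order; in random-ring mode a seeded
    generator produces one ring at a time with a per-ring timeout.
    """
    if mapping is None:
        mapping = ControlMapping()
    if course_spec.kind not in ("obstacle", "random_rings"):
        raise ValueError(f"unknown course kind {course_spec.kind!r}")
    rng = np.random.default_rng(course_spec.seed)
    pose = QuadPose()
    poses = [pose]
    events: list[tuple[float, str]] = []
    rings_crossed = 0
    timeouts = 0

    if course_spec.kind == "obstacle":
        remaining = list(course_spec.rings)
        active = remaining.pop(0) if remaining else None
        ring_clock = 0.0
    else:
        active = _random_ring(rng, course_spec.box)
        ring_clock = 0.0

    n_steps = int(round(max_time / BIN_WIDTH_S))
    for _ in range(n_steps):
        fingers = controller(pose, active, pose.clock)
        cmd = fingers_to_command(fingers, mapping)
        new_pose = step_quadcopter(pose, cmd)
        ring_clock += BIN_WIDTH_S
        if active is not None and ring_crossing(pose, new_pose, active):
            rings_crossed += 1
            events.append((new_pose.clock, "ring"))
            if course_spec.kind == "obstacle":
                active = remaining.pop(0) if remaining else None
            else:
                active = _random_ring(rng, course_spec.box)
            ring_clock = 0.0
        elif course_spec.kind == "random_rings" and ring_clock >= course_spec.ring_timeout:
            timeouts += 1
            events.append((new_pose.clock, "timeout"))
            active = _random_ring(rng, course_spec.box)
            ring_clock = 0.0
        pose = new_pose
        poses.append(pose)
        if course_spec.kind == "obstacle" and active is None:
            break

    total = pose.clock
    return FlightSummary(
        total_time=total,
        rings_crossed=rings_crossed,
        rings_per_min=60.0 * rings_crossed / total if total > 0 else 0.0,
        timeouts=timeouts,
        events=events,
        poses=poses,
    )
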