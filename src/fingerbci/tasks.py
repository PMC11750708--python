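"""Virtual finger tasks: open-loop trajectories, closed-loop trials, and a
simulated user closing the loop in software.

Conventions.  Each finger degree of freedom (DOF) lives in a canonical
position coordinate ``u`` in [0, 1] with neutral at 0.5; the on-screen
convention ``s = 2u - 1`` (full flexion +1, full extension -1) is a display
transform.  Time advances in 50-ms bins.  Trial timing uses start-of-bin
entry times so that, for a successful trial, ``completion_time -
last_entry_time`` equals the required hold exactly.

Task variants:

``cl2d``
    paired center-out/back trials for thumb flexion + index-middle.
``cl4d_two_new`` / ``cl4d_one_new``
    paired 4-DOF trials where two (or one) of the three finger groups get
    new random targets while the remaining group holds its target.
``cl4d_random``
    independent trials, two new random targets each, no pairing.
``t_train``
    the decoder-bootstrapping variant: hold 1.5 s, timeout 5 s, the
    unselected group frozen at center, positions snapped back to center at
    the end of every trial, and every other trial fully stationary at
    center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .population import BIN_WIDTH_S, TuningModel, emit_sbp

__all__ = [
    "DOF_LABELS_2D",
    "DOF_LABELS_4D",
    "FingerState",
    "TargetSet",
    "TrialRecord",
    "TaskConfig",
    "open_loop_trajectory",
    "generate_targets",
    "step_trial",
    "TrialStatus",
    "simulated_user_intent",
    "run_closed_loop_session",
    "oracle_decoder",
    "zero_decoder",
    "finger_groups",
]

DOF_LABELS_4D = ("thumb_flex", "thumb_abd", "index_middle", "ring_little")
DOF_LABELS_2D = ("thumb_flex", "index_middle")

TASK_KINDS = ("cl2d", "cl4d_two_new", "cl4d_one_new", "cl4d_random", "t_train")


def finger_groups(dof_labels: Sequence[str]) -> dict[str, tuple[int, ...]]:
    """Map finger-group name -> DOF indices (the thumb owns two axes in 4D)."""
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(dof_labels):
        name = "thumb" if lab.startswith("thumb") else lab
        groups.setdefault(name, []).append(i)
    return {k: tuple(v) for k, v in groups.items()}


@dataclass
class FingerState:
    positions: np.ndarray                     # u in [0, 1] per DOF
    velocities: np.ndarray                    # ROM-units/s
    dof_labels: tuple[str, ...] = DOF_LABELS_4D

    def __post_init__(self) -> None:
        self.positions = np.clip(np.asarray(self.positions, dtype=float), 0.0, 1.0)
        self.velocities = np.asarray(self.velocities, dtype=float)

    @classmethod
    def neutral(cls, dof_labels: tuple[str, ...] = DOF_LABELS_4D) -> "FingerState":
        d = len(dof_labels)
        return cls(np.full(d, 0.5), np.zeros(d), dof_labels)

    @property
    def display(self) -> np.ndarray:
        """Screen coordinate s = 2u - 1 in [-1, 1]."""
        return 2.0 * self.positions - 1.0


@dataclass(frozen=True)
class TargetSet:
    centers: np.ndarray                       # u units
    width: float = 0.20                       # fraction of ROM
    hold_required: float = 0.5                # s
    timeout: float = 10.0                     # s
    kind: str = "out"                         # out | back | stationary
    cued_groups: tuple[str, ...] = ()
    frozen_dofs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        if self.width <= 0:
            raise ValueError("target width must be > 0")
        if self.hold_required > self.timeout:
            raise ValueError("hold_required must not exceed timeout")

    def inside(self, positions: np.ndarray) -> np.ndarray:
        return np.abs(np.asarray(positions) - self.centers) <= self.width / 2.0


@dataclass
class TrialRecord:
    """One cued trial: targets, per-bin signals, timing events, outcome.

    ``positions`` has one more row than ``decoded_velocities``: row 0 is the
    state at the cue; row ``k`` the state at the end of bin ``k``.  All
    times are in seconds from the cue and are multiples of 50 ms.
    """

    task_kind: str
    target_set: TargetSet
    positions: np.ndarray
    decoded_velocities: np.ndarray
    intents: np.ndarray | None = None
    sbp: np.ndarray | None = None
    cue_time: float = 0.0
    first_entry_time: float | None = None
    last_entry_time: float | None = None
    completion_time: float | None = None
    success: bool = False
    cued_groups: tuple[str, ...] = ()
    trial_index: int = 0
    dof_labels: tuple[str, ...] = DOF_LABELS_4D

    @property
    def duration(self) -> float:
        """Trial length in seconds: completion time if successful, else timeout."""
        return self.completion_time if self.success else self.target_set.timeout


# ------------------------------------------------------------------ open loop


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def open_loop_trajectory(
    cued_dof: int | str,
    direction: str,
    move_time: float = 2.0,
    hold_time: float = 1.0,
    dof_labels: tuple[str, ...] = DOF_LABELS_4D,
) -> np.ndarray:
    """Scripted minimum-jerk move from neutral to full flexion/extension.

    Returns per-bin positions of shape (n_bins + 1, dof) including the
    starting sample: a smooth profile from u = 0.5 to 1 (flex) or 0
    (extend) over ``move_time`` followed by a constant hold, with zero
    endpoint velocities.  Uncued DOF stay at neutral.
    """
    if direction not in ("flex", "extend"):
        raise ValueError("direction must be 'flex' or 'extend'")
    if isinstance(cued_dof, str):
        cued_dof = dof_labels.index(cued_dof)
    if not 0 <= cued_dof < len(dof_labels):
        raise ValueError(f"invalid cued_dof {cued_dof}")
    n_move = int(round(move_time / BIN_WIDTH_S))
    n_hold = int(round(hold_time / BIN_WIDTH_S))
    endpoint = 1.0 if direction == "flex" else 0.0
    tau = np.arange(n_move + 1) / n_move
    profile = 0.5 + (_min_jerk(tau)) * (endpoint - 0.5)
    series = np.concatenate([profile, np.full(n_hold, endpoint)])
    out = np.full((len(series), len(dof_labels)), 0.5)
    out[:, cued_dof] = series
    return out


# ------------------------------------------------------------------- targets


def _random_center(rng: np.random.Generator, width: float) -> float:
    # targets drawn so that center +- width/2 fits inside the range of motion
    return float(rng.uniform(width / 2.0, 1.0 - width / 2.0))


def generate_targets(
    task_kind: str,
    previous: TargetSet | None,
    rng: np.random.Generator,
    width: float = 0.20,
    dof_labels: tuple[str, ...] | None = None,
) -> TargetSet:
    """Targets for the next trial under the variant's pairing rules."""
    if task_kind not in TASK_KINDS:
        raise ValueError(f"unknown task_kind {task_kind!r}")
    if dof_labels is None:
        dof_labels = DOF_LABELS_2D if task_kind == "cl2d" else DOF_LABELS_4D
    d = len(dof_labels)
    groups = finger_groups(dof_labels)
    names = list(groups)
    center = np.full(d, 0.5)

    hold, timeout = (1.5, 5.0) if task_kind == "t_train" else (0.5, 10.0)

    if task_kind == "cl2d":
        if previous is not None and previous.kind == "out":
            return TargetSet(center, width, hold, timeout, "back", tuple(names))
        centers = np.array([_random_center(rng, width) for _ in range(d)])
        return TargetSet(centers, width, hold, timeout, "out", tuple(names))

    if task_kind in ("cl4d_two_new", "cl4d_one_new"):
        n_new = 2 if task_kind == "cl4d_two_new" else 1
        if previous is not None and previous.kind == "out":
            cued = previous.cued_groups
            return TargetSet(center, width, hold, timeout, "back", cued)
        chosen = tuple(sorted(rng.choice(len(names), size=n_new, replace=False)))
        centers = center.copy()
        cued = tuple(names[i] for i in chosen)
        for g in cued:
            for ax in groups[g]:
                centers[ax] = _random_center(rng, width)
        return TargetSet(centers, width, hold, timeout, "out", cued)

    if task_kind == "cl4d_random":
        chosen = tuple(sorted(rng.choice(len(names), size=2, replace=False)))
        centers = (
            previous.centers.copy() if previous is not None else center.copy()
        )
        cued = tuple(names[i] for i in chosen)
        for g in cued:
            for ax in groups[g]:
                centers[ax] = _random_center(rng, width)
        return TargetSet(centers, width, hold, timeout, "out", cued)

    # t_train: alternate two-new-target trials (even indices) with fully
    # stationary center trials; the unselected group is frozen at center on
    # moving trials.
    if previous is not None and previous.kind == "out":
        all_dofs = tuple(range(d))
        return TargetSet(center, width, hold, timeout, "stationary", (), all_dofs)
    chosen = tuple(sorted(rng.choice(len(names), size=2, replace=False)))
    centers = center.copy()
    cued = tuple(names[i] for i in chosen)
    frozen: list[int] = []
    for i, g in enumerate(names):
        if i in chosen:
            for ax in groups[g]:
                centers[ax] = _random_center(rng, width)
        else:
            frozen.extend(groups[g])
    return TargetSet(centers, width, hold, timeout, "out", cued, tuple(frozen))


# --------------------------------------------------------------------- trials


@dataclass
class TrialStatus:
    elapsed_bins: int = 0
    hold_bins: int = 0
    outcome: str = "running"             # running | success | failure
    first_entry_bin: int | None = None   # bin index whose start is the entry
    streak_start_bin: int | None = None


def step_trial(
    state: FingerState,
    decoded_velocity: np.ndarray,
    target_set: TargetSet,
    status: TrialStatus,
) -> TrialStatus:
    """Advance one 50-ms bin of a closed-loop trial (mutates state/status).

    Position integrates the decoded velocity and clamps to [0, 1]; frozen
    DOF do not move.  The trial succeeds once every DOF has been inside its
    target for ``hold_required`` of *consecutive* bins (any exit resets the
    counter) and fails when the clock exceeds the timeout.  Entry times are
    credited at the start of the first inside bin, so a successful trial
    satisfies ``completion - last_entry == hold_required`` exactly.
    """
    if status.outcome != "running":
        return status
    v = np.asarray(decoded_velocity, dtype=float).copy()
    if target_set.frozen_dofs:
        v[list(target_set.frozen_dofs)] = 0.0
    state.velocities = v
    state.positions = np.clip(state.positions + v * BIN_WIDTH_S, 0.0, 1.0)
    k = status.elapsed_bins  # this bin's index; it covers [0.05k, 0.05(k+1))
    if bool(np.all(target_set.inside(state.positions))):
        if status.hold_bins == 0:
            status.streak_start_bin = k
        if status.first_entry_bin is None:
            status.first_entry_bin = k
        status.hold_bins += 1
    else:
        status.hold_bins = 0
        status.streak_start_bin = None
    status.elapsed_bins = k + 1
    hold_bins_required = int(round(target_set.hold_required / BIN_WIDTH_S))
    if status.hold_bins >= hold_bins_required:
        status.outcome = "success"
    elif status.elapsed_bins * BIN_WIDTH_S >= target_set.timeout:
        status.outcome = "failure"
    return status


def simulated_user_intent(
    state: FingerState, target_set: TargetSet, dead_zone: float | None = None
) -> np.ndarray:
    """Unit (or zero) intent vector toward the targets.

    Components for DOF within ``dead_zone`` of their target center are
    zeroed (default dead zone: the target half-width, i.e. inside the
    target); the remainder is normalized to unit length.  Positive
    components mean flexion/abduction.
    """
    if dead_zone is None:
        dead_zone = target_set.width / 2.0
    if dead_zone < 0:
        raise ValueError("dead_zone must be >= 0")
    err = target_set.centers - state.positions
    err = np.where(np.abs(err) <= dead_zone, 0.0, err)
    norm = np.linalg.norm(err)
    if norm == 0.0:
        return np.zeros_like(err)
    return err / norm


# ------------------------------------------------------------------- sessions


@dataclass(frozen=True)
class TaskConfig:
    """Closed-loop session settings for one task variant."""

    task_kind: str = "cl2d"
    width: float = 0.20
    user_speed: float = 1.0          # ROM-units/s along the intent direction
    motor_noise_sd: float = 0.0      # ROM-units/s, per DOF
    dead_zone: float | None = None
    hold_s: float | None = None      # override the task kind's hold requirement
    timeout_s: float | None = None   # override the task kind's timeout

    def dof_labels(self) -> tuple[str, ...]:
        return DOF_LABELS_2D if self.task_kind == "cl2d" else DOF_LABELS_4D


def oracle_decoder(speed: float = 1.0) -> Callable:
    """Perfect controller: returns intent * speed, ignoring the neural data."""

    def _decode(window, intent):
        return np.asarray(intent, dtype=float) * speed

    return _decode


def zero_decoder(window, intent):
    """Null controller: always zero velocity."""
    return np.zeros_like(np.asarray(intent, dtype=float))


def run_closed_loop_session(
    task_cfg: TaskConfig,
    decoder,
    model: TuningModel,
    n_trials: int,
    seed: int = 0,
) -> list[TrialRecord]:
    """Simulate a full closed-loop session and return its trial log.

    Per bin: the simulated user forms a unit intent toward the targets and
    attempts ``intent * user_speed`` (plus optional Gaussian motor noise);
    the population emits SBP for the attempted velocity; the decoder maps
    the 3-bin SBP window to a velocity that drives the fingers.  ``decoder``
    is either a trained :class:`~fingerbci.decoder.Decoder` or a callable
    ``f(window, intent) -> velocity`` (for oracle/null controllers).
    Deterministic for a fixed seed.
    """
    labels = task_cfg.dof_labels()
    d = len(labels)
    if model.dof != d:
        raise ValueError(
            f"population dof ({model.dof}) incompatible with task dof ({d})"
        )
    if hasattr(decoder, "decode"):
        if decoder.config.dof != d:
            raise ValueError(
                f"decoder dof ({decoder.config.dof}) incompatible with task dof ({d})"
            )
        decode = lambda window, intent: decoder.decode(window)
    elif callable(decoder):
        decode = decoder
    else:
        raise ValueError("decoder must be a Decoder or a callable")

    rng = np.random.default_rng(seed)
    state = FingerState.neutral(labels)
    records: list[TrialRecord] = []
    targets: TargetSet | None = None
    for trial_index in range(n_trials):
        targets = generate_targets(
            task_cfg.task_kind, targets, rng, width=task_cfg.width, dof_labels=labels
        )
        if task_cfg.hold_s is not None or task_cfg.timeout_s is not None:
            targets = replace(
                targets,
                hold_required=task_cfg.hold_s or targets.hold_required,
                timeout=task_cfg.timeout_s or targets.timeout,
            )
        status = TrialStatus()
        positions = [state.positions.copy()]
        decoded_log, intent_log, sbp_log = [], [], []
        window: np.ndarray | None = None
        while status.outcome == "running":
            intent = simulated_user_intent(state, targets, task_cfg.dead_zone)
            attempted = intent * task_cfg.user_speed
            if task_cfg.motor_noise_sd > 0:
                attempted = attempted + rng.normal(0, task_cfg.motor_noise_sd, d)
            if targets.frozen_dofs:
                attempted[list(targets.frozen_dofs)] = 0.0
            sbp = emit_sbp(model, attempted, rng)
            if window is None:
                window = np.tile(sbp[:, None], (1, 3)).astype(float)
            else:
                window = np.concatenate([window[:, 1:], sbp[:, None]], axis=1)
            decoded = np.asarray(decode(window, intent), dtype=float)
            status = step_trial(state, decoded, targets, status)
            positions.append(state.positions.copy())
            decoded_log.append(decoded)
            intent_log.append(intent)
            sbp_log.append(sbp)

        success = status.outcome == "success"
        first_entry = (
            status.first_entry_bin * BIN_WIDTH_S
            if status.first_entry_bin is not None
            else None
        )
        last_entry = (
            status.streak_start_bin * BIN_WIDTH_S if success else None
        )
        completion = status.elapsed_bins * BIN_WIDTH_S if success else None
        records.append(
            TrialRecord(
                task_kind=task_cfg.task_kind,
                target_set=targets,
                positions=np.array(positions),
                decoded_velocities=np.array(decoded_log),
                intents=np.array(intent_log),
                sbp=np.array(sbp_log),
                first_entry_time=first_entry,
                last_entry_time=last_entry,
                completion_time=completion,
                success=success,
                cued_groups=targets.cued_groups,
                trial_index=trial_index,
                dof_labels=labels,
            )
        )
        if task_cfg.task_kind == "t_train":
            # end-of-trial snap to center keeps fingers from sticking
            state.positions = np.full(d, 0.5)
            state.velocities = np.zeros(d)
    return records
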