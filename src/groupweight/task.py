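"""Center-out task state machine.

Two variants are implemented.  Variant "T": only peripheral targets,
at the four cardinal directions; each trial starts with a random
freeze period during which decoded velocity is ignored, and the cursor
is reset to the center at trial end.  Variant "K": center and
random-angle peripheral targets alternate without delay, no freeze, no
reset — trajectories form a center-out-and-back series.

A trial succeeds when the cursor stays inside the target disk for
``hold_time`` continuously (the hold clock resets on exit) and fails
when movement time exceeds ``trial_timeout`` (freeze time excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import TaskConfig
from .decoder import CursorVelocity

__all__ = [
    "TrialRecord",
    "CenterOutTask",
    "next_target",
    "integrate_position",
    "CARDINAL_ANGLES",
]

#: variant-T target angles: right, up, left, down
CARDINAL_ANGLES = (0.0, math.pi / 2, math.pi, -math.pi / 2)


@dataclass
class TrialRecord:
    """Outcome and kinematics of one trial."""

    index: int
    target_position: tuple[float, float]
    target_angle: float
    freeze_duration: float
    outcome: str  # "success" | "fail"
    movement_duration: float
    start_position: tuple[float, float]
    trajectory: np.ndarray  # (n_points, 2), movement-phase positions incl. start
    start_bin: int  # first decoder bin of the trial (freeze included)
    movement_start_bin: int  # first non-frozen decoder bin
    end_bin: int  # exclusive
    action_value_series: np.ndarray | None = None  # (n_move_bins, 4)

    @property
    def success(self) -> bool:
        return self.outcome == "success"


def next_target(
    cfg: TaskConfig, previous: TrialRecord | None, rng: np.random.Generator
) -> tuple[tuple[float, float], float]:
    """Draw the next target position and its nominal angle.

    Variant T picks uniformly among the four cardinal peripheral
    targets.  Variant K alternates: a center target follows every
    peripheral one, and peripheral targets appear at angles uniform in
    [0, 2*pi).
    """
    if cfg.variant == "T":
        angle = CARDINAL_ANGLES[int(rng.integers(4))]
        pos = (cfg.target_distance * math.cos(angle), cfg.target_distance * math.sin(angle))
        return pos, angle
    # variant K
    prev_was_periph = previous is not None and previous.target_position != (0.0, 0.0)
    if prev_was_periph:
        return (0.0, 0.0), math.nan  # angle filled in relative to start at trial begin
    angle = float(rng.uniform(0.0, 2 * math.pi))
    angle = math.remainder(angle, 2 * math.pi)
    return (cfg.target_distance * math.cos(angle), cfg.target_distance * math.sin(angle)), angle


def integrate_position(
    position: tuple[float, float], velocity: CursorVelocity, cfg: TaskConfig
) -> tuple[float, float]:
    """Euler step of the cursor, clipped to the workspace rectangle."""
    half_w, half_h = cfg.workspace[0] / 2, cfg.workspace[1] / 2
    x = float(np.clip(position[0] + velocity[0] * cfg.dt, -half_w, half_w))
    y = float(np.clip(position[1] + velocity[1] * cfg.dt, -half_h, half_h))
    return x, y


@dataclass
class _ActiveTrial:
    index: int
    target: tuple[float, float]
    target_angle: float
    freeze_duration: float
    start_position: tuple[float, float]
    start_bin: int
    freeze_elapsed: float = 0.0
    movement_elapsed: float = 0.0
    hold_elapsed: float = 0.0
    movement_start_bin: int | None = None
    trajectory: list[tuple[float, float]] = field(default_factory=list)


class CenterOutTask:
    """Drives trials: call :meth:`step` once per decoder bin.

    The task owns the cursor position.  ``step`` applies the decoded
    velocity (ignored while frozen), advances hold/timeout clocks, and
    returns one of the events ``freeze_active``, ``moving``,
    ``hold_in_progress``, ``success``, ``fail``.  Completed trials
    accumulate in :attr:`trials`.
    """

    def __init__(self, cfg: TaskConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self.position: tuple[float, float] = (0.0, 0.0)
        self.trials: list[TrialRecord] = []
        self._bin = 0
        self._trial: _ActiveTrial | None = None

    # -- trial lifecycle -------------------------------------------------

    def _begin_trial(self) -> None:
        prev = self.trials[-1] if self.trials else None
        target, angle = next_target(self.cfg, prev, self.rng)
        if math.isnan(angle):
            # variant-K center target: direction is from current cursor position
            dx, dy = target[0] - self.position[0], target[1] - self.position[1]
            angle = math.atan2(dy, dx) if (dx, dy) != (0.0, 0.0) else 0.0
        freeze = 0.0
        if self.cfg.variant == "T":
            lo, hi = self.cfg.freeze_range
            freeze = float(self.rng.uniform(lo, hi)) if hi > 0 else 0.0
        self._trial = _ActiveTrial(
            index=len(self.trials),
            target=target,
            target_angle=angle,
            freeze_duration=freeze,
            start_position=self.position,
            start_bin=self._bin,
        )

    def _finish_trial(self, outcome: str) -> None:
        t = self._trial
        assert t is not None
        traj = np.array([t.start_position] + t.trajectory, dtype=float)
        self.trials.append(
            TrialRecord(
                index=t.index,
                target_position=t.target,
                target_angle=t.target_angle,
                freeze_duration=t.freeze_duration,
                outcome=outcome,
                movement_duration=min(t.movement_elapsed, self.cfg.trial_timeout),
                start_position=t.start_position,
                trajectory=traj,
                start_bin=t.start_bin,
                movement_start_bin=t.movement_start_bin
                if t.movement_start_bin is not None else self._bin,
                end_bin=self._bin,
            )
        )
        self._trial = None
        if self.cfg.variant == "T":
            self.position = (0.0, 0.0)

    # -- stepping --------------------------------------------------------

    @property
    def frozen(self) -> bool:
        """True if the *upcoming* bin falls in the freeze period."""
        if self._trial is None:
            self._begin_trial()
        t = self._trial
        return t.freeze_elapsed + self.cfg.dt <= t.freeze_duration

    @property
    def current_target(self) -> tuple[float, float]:
        if self._trial is None:
            self._begin_trial()
        return self._trial.target

    @property
    def current_trial_index(self) -> int:
        if self._trial is None:
            self._begin_trial()
        return self._trial.index

    def _inside_target(self, pos: tuple[float, float]) -> bool:
        t = self._trial
        return math.hypot(pos[0] - t.target[0], pos[1] - t.target[1]) <= self.cfg.target_radius

    def step(self, velocity: CursorVelocity) -> str:
        """Advance one bin of dt seconds under the decoded velocity."""
        if self._trial is None:
            self._begin_trial()
        t = self._trial
        cfg = self.cfg
        event: str
        if t.freeze_elapsed + cfg.dt <= t.freeze_duration:
            t.freeze_elapsed += cfg.dt
            event = "freeze_active"
        else:
            if t.movement_start_bin is None:
                t.movement_start_bin = self._bin
            self.position = integrate_position(self.position, velocity, cfg)
            t.trajectory.append(self.position)
            t.movement_elapsed += cfg.dt
            if self._inside_target(self.position):
                t.hold_elapsed += cfg.dt
            else:
                t.hold_elapsed = 0.0
            if t.hold_elapsed >= cfg.hold_time - 1e-12:
                event = "success"
            elif t.movement_elapsed > cfg.trial_timeout + 1e-12:
                event = "fail"
            elif t.hold_elapsed > 0:
                event = "hold_in_progress"
            else:
                event = "moving"
        self._bin += 1
        if event in ("success", "fail"):
            self._finish_trial(event)
        return event
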