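"""Synthetic adaptive spiking population and closed-loop simulation.

This module is the stand-in for recorded multi-unit data: a population
of cosine-tuned Poisson units driven by a simulated user whose intent
points straight at the current target.  Each unit fires at

    rate = max(0, baseline + depth * cos(theta_intent - PD) + noise),

falling back to baseline (+ noise) whenever there is no intent (freeze
periods, disengaged bins, idle recordings).  Spikes are Poisson draws
in 10 ms bins; the decoder consumes their 100 ms sums.

Learning is imposed, not emergent: between sessions each *direct*
unit's preferred direction rotates along the shorter arc toward its
assigned direction and its rate noise is annealed.  This generates
session series carrying the statistical signatures (rising success
rate, rising output-potent values, rising tuning R^2, shrinking
|PD - AD|) that the analysis module is built to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import DecoderConfig, LearningSchedule, PopulationConfig, TaskConfig
from .decoder import Decoder, GroupSpec, estimate_normalization
from .frames import SPIKE_BIN_WIDTH, SpikeFrame
from .grouping import sector_center
from .session_log import FRAME_COLUMNS, SessionLog
from .task import CenterOutTask

__all__ = [
    "SyntheticUnit",
    "make_population",
    "population_group_spec",
    "intent_direction",
    "unit_rate",
    "sample_spikes",
    "advance_learning",
    "generate_idle_frame",
    "run_closed_loop_session",
    "run_training",
]


@dataclass(frozen=True)
class SyntheticUnit:
    """One cosine-tuned multi-unit."""

    channel_id: str
    baseline_rate: float
    modulation_depth: float
    pd_angle: float
    rate_noise_sd: float
    assigned_direction: float | None = None

    @property
    def direct(self) -> bool:
        return self.assigned_direction is not None


def make_population(
    cfg: PopulationConfig | None = None, rng: np.random.Generator | None = None
) -> list[SyntheticUnit]:
    """Build the default population: direct units per sector plus
    weakly tuned indirect units.

    Direct units get their sector center as assigned direction (AD) and
    a preferred direction inside the sector but offset from the AD by a
    random angle in ``cfg.pd_offset_range`` (random sign) — they are
    plausibly selectable by sector membership yet initially misaligned.
    """
    cfg = cfg or PopulationConfig()
    rng = rng or np.random.default_rng(0)
    units: list[SyntheticUnit] = []
    lo, hi = cfg.pd_offset_range
    for lab in ("right", "left", "up", "down"):
        ad = sector_center(lab)
        for j in range(cfg.n_direct_per_group):
            offset = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
            pd_angle = math.remainder(ad + offset, 2 * math.pi)
            units.append(
                SyntheticUnit(
                    channel_id=f"d_{lab}_{j}",
                    baseline_rate=cfg.baseline_rate,
                    modulation_depth=cfg.modulation_depth,
                    pd_angle=pd_angle,
                    rate_noise_sd=cfg.rate_noise_sd,
                    assigned_direction=ad,
                )
            )
    for j in range(cfg.n_indirect):
        units.append(
            SyntheticUnit(
                channel_id=f"i_{j:02d}",
                baseline_rate=cfg.baseline_rate,
                modulation_depth=cfg.indirect_depth,
                pd_angle=float(rng.uniform(-math.pi, math.pi)),
                rate_noise_sd=cfg.indirect_noise_sd,
                assigned_direction=None,
            )
        )
    return units


def population_group_spec(units: list[SyntheticUnit]) -> GroupSpec:
    """GroupSpec from the units' assigned directions (mu/delta unset)."""
    groups = []
    for lab in ("right", "left", "up", "down"):
        ad = sector_center(lab)
        idx = tuple(
            i for i, u in enumerate(units)
            if u.direct and math.isclose(math.remainder(u.assigned_direction - ad, 2 * math.pi), 0.0, abs_tol=1e-9)
        )
        groups.append(idx)
    return GroupSpec(tuple(groups))


def intent_direction(
    position: tuple[float, float], target: tuple[float, float], frozen: bool = False
) -> np.ndarray | None:
    """Unit vector from cursor to target center; None when frozen or
    already at the target."""
    if frozen:
        return None
    dx, dy = target[0] - position[0], target[1] - position[1]
    norm = math.hypot(dx, dy)
    if norm == 0.0:
        return None
    return np.array([dx / norm, dy / norm])


def unit_rate(
    unit: SyntheticUnit,
    intent: np.ndarray | None,
    rng: np.random.Generator | None = None,
) -> float:
    """Instantaneous firing rate (Hz), rectified at zero."""
    rate = unit.baseline_rate
    if intent is not None:
        theta = math.atan2(intent[1], intent[0])
        rate += unit.modulation_depth * math.cos(theta - unit.pd_angle)
    if rng is not None and unit.rate_noise_sd > 0:
        rate += float(rng.normal(0.0, unit.rate_noise_sd))
    return max(rate, 0.0)


def sample_spikes(
    rate: float, bin_width: float = SPIKE_BIN_WIDTH, rng: np.random.Generator | None = None
) -> int:
    """Poisson spike count for one bin at the given rate."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = rng or np.random.default_rng()
    return int(rng.poisson(rate * bin_width))


def advance_learning(
    units: list[SyntheticUnit], schedule: LearningSchedule
) -> list[SyntheticUnit]:
    """One between-session learning step.

    Direct units rotate their PD along the shorter arc toward the AD by
    at most ``pd_rotation_per_session`` (never overshooting) and their
    rate noise SD is multiplied by ``noise_decay_per_session``.
    Indirect units are untouched.
    """
    out = []
    for u in units:
        if not u.direct:
            out.append(u)
            continue
        diff = math.remainder(u.assigned_direction - u.pd_angle, 2 * math.pi)
        step = math.copysign(min(schedule.pd_rotation_per_session, abs(diff)), diff)
        out.append(
            replace(
                u,
                pd_angle=math.remainder(u.pd_angle + step, 2 * math.pi),
                rate_noise_sd=u.rate_noise_sd * schedule.noise_decay_per_session,
            )
        )
    return out


# -- vectorized population sampling -------------------------------------

def _unit_arrays(units: list[SyntheticUnit]):
    base = np.array([u.baseline_rate for u in units])
    depth = np.array([u.modulation_depth for u in units])
    pds = np.array([u.pd_angle for u in units])
    noise = np.array([u.rate_noise_sd for u in units])
    return base, depth, pds, noise


def _population_rates(
    base, depth, pds, noise, intent_angle: float | None, rng: np.random.Generator
) -> np.ndarray:
    rates = base.copy()
    if intent_angle is not None:
        rates = rates + depth * np.cos(intent_angle - pds)
    rates = rates + rng.normal(0.0, 1.0, size=base.shape) * noise
    return np.maximum(rates, 0.0)


def generate_idle_frame(
    units: list[SyntheticUnit], duration: float, rng: np.random.Generator
) -> SpikeFrame:
    """Spikes recorded with no task-directed intent (baseline + noise).

    Noise is drawn once per 100 ms (matching the closed-loop generator)
    and spikes are Poisson per 10 ms bin.
    """
    base, depth, pds, noise = _unit_arrays(units)
    n100 = int(round(duration / 0.1))
    sub = int(round(0.1 / SPIKE_BIN_WIDTH))
    counts = np.zeros((n100 * sub, len(units)), dtype=np.int64)
    for b in range(n100):
        rates = _population_rates(base, depth, pds, noise, None, rng)
        counts[b * sub:(b + 1) * sub] = rng.poisson(rates * SPIKE_BIN_WIDTH, size=(sub, len(units)))
    return SpikeFrame(counts, channel_ids=[u.channel_id for u in units])


def run_closed_loop_session(
    units: list[SyntheticUnit],
    groups: GroupSpec,
    decoder_cfg: DecoderConfig,
    task_cfg: TaskConfig,
    duration: float,
    rng: np.random.Generator,
    engagement: float = 1.0,
    session_index: int = 0,
    seed: int = -1,
) -> SessionLog:
    """Run one closed-loop session and return its full log.

    Per 100 ms bin: intent (straight to target; absent while frozen or
    on disengaged bins) -> unit rates -> ten 10 ms Poisson spike bins
    -> decoder step -> position integration -> task events.
    """
    if not groups.normalized:
        raise ValueError("groups must be normalized (run a pre-experiment first)")
    base, depth, pds, noise = _unit_arrays(units)
    n_units = len(units)
    n_bins = int(round(duration / task_cfg.dt))
    sub = int(round(task_cfg.dt / SPIKE_BIN_WIDTH))
    task = CenterOutTask(task_cfg, rng)
    dec = Decoder(groups, decoder_cfg, n_channels=n_units)
    counts10 = np.zeros((n_bins * sub, n_units), dtype=np.int64)
    frame_rows = np.empty((n_bins, len(FRAME_COLUMNS)))
    for b in range(n_bins):
        frozen = task.frozen
        trial_index = task.current_trial_index
        engaged = (not frozen) and (engagement >= 1.0 or rng.random() < engagement)
        intent_angle = None
        if engaged:
            vec = intent_direction(task.position, task.current_target, frozen)
            if vec is not None:
                intent_angle = math.atan2(vec[1], vec[0])
        rates = _population_rates(base, depth, pds, noise, intent_angle, rng)
        spikes = rng.poisson(rates * SPIKE_BIN_WIDTH, size=(sub, n_units))
        counts10[b * sub:(b + 1) * sub] = spikes
        a, v = dec.step(spikes.sum(axis=0))
        task.step(v)
        frame_rows[b] = (
            b, b * task_cfg.dt, a.a[0], a.a[1], a.a[2], a.a[3],
            v.vx, v.vy, task.position[0], task.position[1],
            trial_index, float(frozen),
        )
    frames = pd.DataFrame(frame_rows, columns=FRAME_COLUMNS)
    frames["bin"] = frames["bin"].astype(int)
    frames["trial_index"] = frames["trial_index"].astype(int)
    frames["frozen"] = frames["frozen"].astype(bool)
    log = SessionLog(
        session_index=session_index,
        seed=seed,
        decoder_cfg=decoder_cfg,
        task_cfg=task_cfg,
        group_spec=groups,
        spikes=SpikeFrame(counts10, channel_ids=[u.channel_id for u in units]),
        frames=frames,
        trials=task.trials,
    )
    log.validate()
    return log


def run_training(
    units: list[SyntheticUnit],
    schedule: LearningSchedule,
    n_sessions: int,
    decoder_cfg: DecoderConfig,
    task_cfg: TaskConfig,
    rng: np.random.Generator | int,
    session_duration: float = 180.0,
    pre_experiment_duration: float = 60.0,
    groups: GroupSpec | None = None,
) -> tuple[list[SessionLog], list[list[SyntheticUnit]]]:
    """Run a multi-session training series with chained normalization.

    Session ``i``'s normalization constants come from its own
    pre-experiment segment; that segment itself runs closed-loop under
    session ``i-1``'s constants.  Session 1's constants come from an
    idle recording.  ``advance_learning`` is applied between sessions.

    Returns the per-session logs and the unit population *as of each
    session* (useful for PD-vs-AD bookkeeping).
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    seed = -1
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    if groups is None:
        groups = population_group_spec(units)
    idle = generate_idle_frame(units, pre_experiment_duration, rng)
    mu, delta = estimate_normalization(idle, groups, decoder_cfg)
    prev_norm = (mu, delta)
    pre_frame = idle
    logs: list[SessionLog] = []
    unit_history: list[list[SyntheticUnit]] = []
    for i in range(1, n_sessions + 1):
        if i > 1:
            pre_log = run_closed_loop_session(
                units, groups.with_normalization(*prev_norm), decoder_cfg, task_cfg,
                pre_experiment_duration, rng, engagement=schedule.engagement,
                session_index=i, seed=seed,
            )
            pre_frame = pre_log.spikes
            prev_norm = estimate_normalization(pre_frame, groups, decoder_cfg)
        gs = groups.with_normalization(*prev_norm)
        log = run_closed_loop_session(
            units, gs, decoder_cfg, task_cfg, session_duration, rng,
            engagement=schedule.engagement, session_index=i, seed=seed,
        )
        log.pre_experiment = pre_frame
        log.meta["n_direct"] = int(sum(u.direct for u in units))
        logs.append(log)
        unit_history.append(list(units))
        units = advance_learning(units, schedule)
    return logs, unit_history
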