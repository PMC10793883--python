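"""Velocity-tuning estimation and sector-based group assignment.

Units are characterised by the linear velocity-encoding model

    fr = b0 + b1 * vx + b2 * vy,

whose coefficient vector (b1, b2) is the unit's preferred-direction
(PD) vector.  The (b1, b2) plane is divided into four equal sectors
with boundaries at the odd multiples of pi/4; each sector corresponds
to one cursor direction.  Stable (> ``stability_days`` days recorded),
tuned units with the largest PD magnitude populate each group; a
sector short of units borrows the nearest-by-angle unassigned eligible
unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .decoder import GROUP_LABELS, GroupSpec

__all__ = [
    "VelocityTuningFit",
    "UnitRecord",
    "fit_velocity_tuning",
    "preferred_direction",
    "sector_of",
    "sector_center",
    "select_groups",
    "read_unit_table",
    "write_unit_table",
]

_SECTOR_CENTERS = {"right": 0.0, "up": math.pi / 2, "left": math.pi, "down": -math.pi / 2}


@dataclass(frozen=True)
class VelocityTuningFit:
    """OLS fit of firing rate on cursor velocity."""

    b0: float
    b1: float
    b2: float
    r2: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError(f"r2 out of [0, 1]: {self.r2}")


@dataclass(frozen=True)
class UnitRecord:
    """One unit's identity, recording stability, and tuning summary."""

    channel_id: str
    days_recorded: int
    fit: VelocityTuningFit
    pd_angle: float
    pd_magnitude: float
    untuned: bool = False

    def __post_init__(self) -> None:
        if self.pd_magnitude < 0:
            raise ValueError("pd_magnitude must be >= 0")


def fit_velocity_tuning(rates: np.ndarray, velocities: np.ndarray) -> VelocityTuningFit:
    """Ordinary least squares of rate (Hz) on (1, vx, vy).

    Raises ``ValueError`` on fewer than 3 bins or a rank-deficient
    design (constant or collinear velocities).
    """
    rates = np.asarray(rates, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if velocities.ndim != 2 or velocities.shape[1] != 2:
        raise ValueError("velocities must have shape (n_bins, 2)")
    n = rates.shape[0]
    if n < 3 or velocities.shape[0] != n:
        raise ValueError(f"need >= 3 matched bins, got {rates.shape[0]} rates "
                         f"and {velocities.shape[0]} velocities")
    X = np.column_stack([np.ones(n), velocities])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: velocities constant or collinear")
    beta, _, _, _ = np.linalg.lstsq(X, rates, rcond=None)
    resid = rates - X @ beta
    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return VelocityTuningFit(float(beta[0]), float(beta[1]), float(beta[2]),
                             float(np.clip(r2, 0.0, 1.0)))


def preferred_direction(fit: VelocityTuningFit) -> tuple[float, float]:
    """PD angle (radians, atan2 convention) and magnitude of (b1, b2).

    A zero coefficient vector has no direction; such units are flagged
    untuned by raising ``ValueError`` (callers exclude them from
    grouping).
    """
    mag = math.hypot(fit.b1, fit.b2)
    if mag == 0.0:
        raise ValueError("zero (b1, b2) vector: unit is untuned")
    return math.atan2(fit.b2, fit.b1), mag


def sector_of(angle: float) -> str:
    """Direction label of the sector containing ``angle``.

    Sectors are half-open, counter-clockwise inclusive: right is
    [-pi/4, pi/4), up is [pi/4, 3pi/4), left is [3pi/4, 5pi/4), down is
    [5pi/4, 7pi/4); every angle maps to exactly one sector.
    """
    if not math.isfinite(angle):
        raise ValueError("angle must be finite")
    # rotate so sector boundaries fall on quadrant boundaries
    idx = int(math.floor((angle + math.pi / 4) / (math.pi / 2))) % 4
    return ("right", "up", "left", "down")[idx]


def sector_center(label: str) -> float:
    return _SECTOR_CENTERS[label]


def _angdist(a: float, b: float) -> float:
    """Absolute angular distance on the circle, in [0, pi]."""
    return abs(math.remainder(a - b, 2 * math.pi))


def select_groups(
    units: list[UnitRecord],
    n_per_group: int = 4,
    stability_days: int = 5,
) -> tuple[GroupSpec, dict[str, list[UnitRecord]]]:
    """Assign stable, strongly tuned units to the four direction groups.

    Eligibility is strict: ``days_recorded > stability_days`` and a
    nonzero PD.  Each sector takes its ``n_per_group`` largest-magnitude
    in-sector units; shortfalls are filled with the nearest
    eligible unassigned units by angular distance to the sector center
    (ties broken by channel_id).  Returns the GroupSpec (mu/delta
    unset, channel indices refer to positions in ``units``) and the
    per-label member lists.
    """
    eligible = [
        (i, u) for i, u in enumerate(units)
        if u.days_recorded > stability_days and not u.untuned and u.pd_magnitude > 0
    ]
    needed = 4 * n_per_group
    if len(eligible) < needed:
        raise ValueError(
            f"not enough eligible units: need {needed}, have {len(eligible)} "
            f"(of {len(units)} total)"
        )
    assigned: dict[str, list[int]] = {lab: [] for lab in GROUP_LABELS}
    taken: set[int] = set()
    # first pass: strongest in-sector units
    for lab in GROUP_LABELS:
        in_sector = [(i, u) for i, u in eligible if sector_of(u.pd_angle) == lab]
        in_sector.sort(key=lambda iu: (-iu[1].pd_magnitude, iu[1].channel_id))
        for i, _u in in_sector[:n_per_group]:
            assigned[lab].append(i)
            taken.add(i)
    # second pass: borrow nearby units for short sectors
    for lab in GROUP_LABELS:
        while len(assigned[lab]) < n_per_group:
            center = _SECTOR_CENTERS[lab]
            pool = [(i, u) for i, u in eligible if i not in taken]
            pool.sort(key=lambda iu: (_angdist(iu[1].pd_angle, center), iu[1].channel_id))
            i, _u = pool[0]
            assigned[lab].append(i)
            taken.add(i)
    spec = GroupSpec(tuple(tuple(sorted(assigned[lab])) for lab in GROUP_LABELS))
    members = {lab: [units[i] for i in assigned[lab]] for lab in GROUP_LABELS}
    return spec, members


# -- unit table CSV ------------------------------------------------------

_TABLE_COLUMNS = [
    "channel_id", "days_recorded", "b0", "b1", "b2", "r2",
    "pd_angle", "pd_magnitude", "assigned_group",
]


def write_unit_table(
    units: list[UnitRecord],
    path: str | Path,
    assignment: dict[str, list[UnitRecord]] | None = None,
) -> None:
    group_of: dict[str, str] = {}
    if assignment:
        for lab, members in assignment.items():
            for u in members:
                group_of[u.channel_id] = lab
    rows = [
        {
            "channel_id": u.channel_id,
            "days_recorded": u.days_recorded,
            "b0": u.fit.b0, "b1": u.fit.b1, "b2": u.fit.b2, "r2": u.fit.r2,
            "pd_angle": u.pd_angle, "pd_magnitude": u.pd_magnitude,
            "assigned_group": group_of.get(u.channel_id, ""),
        }
        for u in units
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


def read_unit_table(path: str | Path) -> list[UnitRecord]:
    df = pd.read_csv(path, dtype={"channel_id": str}, keep_default_na=False)
    missing = set(_TABLE_COLUMNS) - {"assigned_group"} - set(df.columns)
    if missing:
        raise ValueError(f"unit table missing columns: {sorted(missing)}")
    units = []
    for row in df.itertuples(index=False):
        fit = VelocityTuningFit(float(row.b0), float(row.b1), float(row.b2), float(row.r2))
        mag = float(row.pd_magnitude)
        units.append(
            UnitRecord(
                channel_id=str(row.channel_id),
                days_recorded=int(row.days_recorded),
                fit=fit,
                pd_angle=float(row.pd_angle),
                pd_magnitude=mag,
                untuned=mag == 0.0,
            )
        )
    return units
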