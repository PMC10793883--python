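"""Configuration objects for the decoder, task, population, and runs.

All sections are plain dataclasses with eager validation.  ``RunConfig``
round-trips to/from dicts (and YAML/JSON files) with strict key checking:
unknown keys are rejected so a typo in a run file fails loudly instead of
silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "DecoderConfig",
    "TaskConfig",
    "PopulationConfig",
    "LearningSchedule",
    "BaselineConfig",
    "RunConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration value or key is invalid."""


@dataclass(frozen=True)
class DecoderConfig:
    """Constants of the group-weight decoder.

    Parameters
    ----------
    bin_width
        Width of a decoder bin in seconds.  Spike counts are consumed on
        this grid (default 100 ms).
    smoothing_bins
        Length of the trailing moving-average window applied to binned
        counts before conversion to rates (default 5 bins = 500 ms).
    c
        Dimensionless offset added to the z-scored group rate before
        rectification.  With c = 1 a group at its pre-experiment mean
        produces an action value of 1.
    w
        Gain from net action value to cursor speed, cm/s per unit.
    v_max
        Per-axis speed clamp, cm/s.
    delta_floor
        Minimum allowed normalization SD in Hz; near-constant
        pre-experiment segments are floored here to avoid division
        blow-up.
    normalize_on_smoothed
        If True, the normalization SD is computed on the smoothed
        group-sum series (the signal the decoder sees at run time);
        if False (default) on the raw binned sums.  The raw choice
        calibrates the decoder so that stationary input yields mean
        action value ~ c and mean velocity ~ 0.
    """

    bin_width: float = 0.1
    smoothing_bins: int = 5
    c: float = 1.0
    w: float = 0.375
    v_max: float = 15.0
    delta_floor: float = 0.1
    normalize_on_smoothed: bool = False

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ConfigError(f"bin_width must be > 0, got {self.bin_width}")
        if int(self.smoothing_bins) != self.smoothing_bins or self.smoothing_bins < 1:
            raise ConfigError(f"smoothing_bins must be an integer >= 1, got {self.smoothing_bins}")
        if not self.v_max > 0:
            raise ConfigError(f"v_max must be > 0, got {self.v_max}")
        if not self.delta_floor > 0:
            raise ConfigError(f"delta_floor must be > 0, got {self.delta_floor}")


@dataclass(frozen=True)
class TaskConfig:
    """Center-out task geometry and timing.

    ``variant`` selects between the two task layouts: "T" shows only
    peripheral targets at the four cardinal directions, freezes the
    cursor for a random delay before each movement, and resets it to
    the center after every trial; "K" alternates center and
    random-angle peripheral targets with no freeze and no reset.
    Timeout excludes the freeze period.  Geometry defaults (target
    distance 7 cm, radius 1.5 cm, 30 x 25 cm workspace) are
    configurable; the hold and timeout defaults are the task's
    published timing.
    """

    variant: str = "T"
    target_radius: float = 1.5
    target_distance: float = 7.0
    hold_time: float = 0.2
    trial_timeout: float = 15.0
    freeze_range: tuple[float, float] = (2.5, 5.0)
    workspace: tuple[float, float] = (30.0, 25.0)
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.variant not in ("T", "K"):
            raise ConfigError(f"variant must be 'T' or 'K', got {self.variant!r}")
        if not self.hold_time > 0:
            raise ConfigError(f"hold_time must be > 0, got {self.hold_time}")
        if not self.trial_timeout > 0:
            raise ConfigError(f"trial_timeout must be > 0, got {self.trial_timeout}")
        if not self.dt > 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        if not 0 < self.target_radius < self.target_distance:
            raise ConfigError("need 0 < target_radius < target_distance")
        half_w, half_h = self.workspace[0] / 2, self.workspace[1] / 2
        if self.target_distance + self.target_radius > min(half_w, half_h):
            raise ConfigError("target geometry does not fit inside the workspace")
        lo, hi = self.freeze_range
        if lo < 0 or hi < lo:
            raise ConfigError(f"freeze_range must be 0 <= lo <= hi, got {self.freeze_range}")


@dataclass(frozen=True)
class PopulationConfig:
    """Synthetic multi-unit population layout.

    Four direct units per sector drive the decoder; indirect units are
    recorded but never enter a group.  Rates are in Hz.  Direct units
    start with preferred directions inside their assigned sector but
    offset from its center by ``pd_offset_range`` (radians), emulating
    units selected by sector membership rather than perfect alignment.
    """

    n_direct_per_group: int = 4
    n_indirect: int = 16
    baseline_rate: float = 10.0
    modulation_depth: float = 8.0
    indirect_depth: float = 1.5
    rate_noise_sd: float = 5.0
    indirect_noise_sd: float = 2.0
    pd_offset_range: tuple[float, float] = (math.radians(45.0), math.radians(135.0))

    def __post_init__(self) -> None:
        if self.n_direct_per_group < 1:
            raise ConfigError("n_direct_per_group must be >= 1")
        for name in ("baseline_rate", "modulation_depth", "indirect_depth",
                     "rate_noise_sd", "indirect_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LearningSchedule:
    """Imposed learning dynamics applied between sessions.

    ``pd_rotation_per_session`` rotates each direct unit's preferred
    direction along the shorter arc toward its assigned direction;
    ``noise_decay_per_session`` multiplies the per-unit rate noise SD;
    ``engagement`` is the per-bin probability that the simulated user
    aims at the target.  ``LearningSchedule.null()`` (rotation 0,
    decay 1) is the no-learning control condition.
    """

    pd_rotation_per_session: float = math.radians(11.0)
    noise_decay_per_session: float = 0.82
    engagement: float = 0.85

    def __post_init__(self) -> None:
        if self.pd_rotation_per_session < 0:
            raise ConfigError("pd_rotation_per_session must be >= 0")
        if not 0 < self.noise_decay_per_session <= 1:
            raise ConfigError("noise_decay_per_session must be in (0, 1]")
        if not 0 <= self.engagement <= 1:
            raise ConfigError("engagement must be in [0, 1]")

    @classmethod
    def null(cls, engagement: float = 0.85) -> "LearningSchedule":
        return cls(pd_rotation_per_session=0.0, noise_decay_per_session=1.0,
                   engagement=engagement)


@dataclass(frozen=True)
class BaselineConfig:
    """Chance-level replay settings: trial duration is fixed (10 s)."""

    trial_duration: float = 10.0
    n_shuffles: int = 1

    def __post_init__(self) -> None:
        if not self.trial_duration > 0:
            raise ConfigError("trial_duration must be > 0")
        if self.n_shuffles < 1:
            raise ConfigError("n_shuffles must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Top-level run description: all sections plus durations and seed."""

    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    schedule: LearningSchedule = field(default_factory=LearningSchedule)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    n_sessions: int = 12
    session_duration: float = 180.0
    pre_experiment_duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ConfigError("n_sessions must be >= 1")
        if not self.session_duration > 0 or not self.pre_experiment_duration > 0:
            raise ConfigError("durations must be > 0")

    # -- dict / file round-trip ------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key, value in list(d.items()):
            if isinstance(value, tuple):
                d[key] = list(value)
            elif isinstance(value, dict):
                d[key] = {k: list(v) if isinstance(v, tuple) else v for k, v in value.items()}
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        sections = {
            "decoder": DecoderConfig,
            "task": TaskConfig,
            "population": PopulationConfig,
            "schedule": LearningSchedule,
            "baseline": BaselineConfig,
        }
        kwargs: dict[str, Any] = {}
        scalar_keys = {f.name for f in dataclasses.fields(cls)} - set(sections)
        for key, value in data.items():
            if key in sections:
                kwargs[key] = _build_section(sections[key], value, key)
            elif key in scalar_keys:
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown top-level config key: {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _build_section(section_cls: type, value: Any, name: str) -> Any:
    if isinstance(value, section_cls):
        return value
    if not isinstance(value, dict):
        raise ConfigError(f"config section {name!r} must be a mapping")
    valid = {f.name: f for f in dataclasses.fields(section_cls)}
    kwargs = {}
    for key, v in value.items():
        if key not in valid:
            raise ConfigError(f"unknown key {key!r} in config section {name!r}")
        if isinstance(v, list):
            v = tuple(v)
        kwargs[key] = v
    return section_cls(**kwargs)
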