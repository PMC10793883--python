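"""The group-weight decoder.

Four groups of channels drive the four cardinal directions of a 2-D
cursor, one opposing pair per axis, like agonist/antagonist muscle
groups.  Each 100 ms the decoder smooths the binned spike counts with a
trailing 5-bin moving average, sums firing rates within each group,
z-scores the sum against pre-experiment statistics, offsets by ``c``
and rectifies at zero to obtain an *action value*

    a_k = max((sum_i fr_i - mu_k) / delta_k + c, 0),

and converts net action values to velocity

    v_x = w * (a_1 - a_2),   v_y = w * (a_3 - a_4),

clamped per axis to +/- v_max.  Group order is fixed: k = 1..4 is
(right, left, up, down), i.e. (+x, -x, +y, -y).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .config import DecoderConfig
from .frames import SpikeFrame

__all__ = [
    "GROUP_LABELS",
    "GroupSpec",
    "ActionValues",
    "CursorVelocity",
    "DecoderState",
    "Decoder",
    "smooth_firing_rates",
    "action_value",
    "decode_velocity",
    "estimate_normalization",
]

#: fixed group order: index 0..3 drives +x, -x, +y, -y
GROUP_LABELS = ("right", "left", "up", "down")


class CursorVelocity(NamedTuple):
    vx: float
    vy: float


@dataclass(frozen=True)
class ActionValues:
    """The four non-negative normalized group firing rates a_1..a_4."""

    a: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"expected 4 action values, got shape {a.shape}")
        if np.any(a < 0):
            raise ValueError("action values must be non-negative (rectified)")
        object.__setattr__(self, "a", a)

    def __iter__(self):
        return iter(self.a)


@dataclass(frozen=True)
class GroupSpec:
    """Channel-to-group assignment with per-group normalization constants.

    ``groups`` holds four ordered tuples of channel indices (columns of
    the SpikeFrame), in the fixed (right, left, up, down) order.  ``mu``
    and ``delta`` are the per-group mean and SD of the summed firing
    rate in Hz; both are None until normalization has been estimated.
    """

    groups: tuple[tuple[int, ...], ...]
    mu: np.ndarray | None = None
    delta: np.ndarray | None = None

    def __post_init__(self) -> None:
        groups = tuple(tuple(int(i) for i in g) for g in self.groups)
        if len(groups) != 4:
            raise ValueError(f"expected exactly 4 groups, got {len(groups)}")
        flat = [i for g in groups for i in g]
        if len(flat) != len(set(flat)):
            raise ValueError("groups must be pairwise disjoint")
        object.__setattr__(self, "groups", groups)
        for name in ("mu", "delta"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (4,):
                    raise ValueError(f"{name} must have shape (4,)")
                object.__setattr__(self, name, v)
        if self.delta is not None and np.any(self.delta <= 0):
            raise ValueError("delta must be positive (apply the floor first)")

    @property
    def normalized(self) -> bool:
        return self.mu is not None and self.delta is not None

    @property
    def channels(self) -> list[int]:
        return [i for g in self.groups for i in g]

    def with_normalization(self, mu: np.ndarray, delta: np.ndarray) -> "GroupSpec":
        return replace(self, mu=np.asarray(mu, float), delta=np.asarray(delta, float))

    def summed_rates(self, rates: np.ndarray) -> np.ndarray:
        """Sum per-channel rates (last axis) within each group."""
        rates = np.asarray(rates, dtype=float)
        return np.stack([rates[..., list(g)].sum(axis=-1) for g in self.groups], axis=-1)


@dataclass
class DecoderState:
    """Trailing window of per-channel binned counts (moving-average memory)."""

    n_channels: int
    smoothing_bins: int = 5
    count_buffer: deque = field(init=False)

    def __post_init__(self) -> None:
        self.count_buffer = deque(maxlen=self.smoothing_bins)

    def push(self, new_counts: np.ndarray) -> np.ndarray:
        counts = np.asarray(new_counts)
        if counts.shape != (self.n_channels,):
            raise ValueError(
                f"expected counts of shape ({self.n_channels},), got {counts.shape}"
            )
        if np.any(counts < 0) or not np.all(counts == np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        self.count_buffer.append(counts.astype(np.int64))
        return self.window_sum()

    def window_sum(self) -> np.ndarray:
        if not self.count_buffer:
            return np.zeros(self.n_channels, dtype=np.int64)
        return np.sum(self.count_buffer, axis=0)


def smooth_firing_rates(
    state: DecoderState, new_counts: np.ndarray, cfg: DecoderConfig
) -> np.ndarray:
    """Push one bin of counts and return per-channel smoothed rates (Hz).

    The window is zero-padded to ``smoothing_bins`` at session start, so
    the rate is always (window count sum) / (smoothing_bins * bin_width).
    """
    total = state.push(new_counts)
    return total / (cfg.smoothing_bins * cfg.bin_width)


def action_value(summed_rate: float, mu: float, delta: float, c: float) -> float:
    """Normalized, offset, rectified group firing rate."""
    if np.any(np.asarray(delta) <= 0):
        raise ValueError("delta must be > 0 (normalization not estimated?)")
    return np.maximum((summed_rate - mu) / delta + c, 0.0)


def decode_velocity(a: ActionValues | np.ndarray, cfg: DecoderConfig) -> CursorVelocity:
    """Map action values to per-axis clamped cursor velocity (cm/s)."""
    arr = a.a if isinstance(a, ActionValues) else np.asarray(a, dtype=float)
    vx = float(np.clip(cfg.w * (arr[0] - arr[1]), -cfg.v_max, cfg.v_max))
    vy = float(np.clip(cfg.w * (arr[2] - arr[3]), -cfg.v_max, cfg.v_max))
    return CursorVelocity(vx, vy)


def _group_sum_series(
    frame: SpikeFrame, groups: GroupSpec | Sequence[Iterable[int]], cfg: DecoderConfig
) -> np.ndarray:
    """(n_decoder_bins, 4) raw group-summed rate series in Hz."""
    if not isinstance(groups, GroupSpec):
        groups = GroupSpec(tuple(tuple(g) for g in groups))
    factor = int(round(cfg.bin_width / frame.bin_width))
    counts = frame.counts
    n = (counts.shape[0] // factor) * factor
    binned = counts[:n].reshape(-1, factor, counts.shape[1]).sum(axis=1)
    rates = binned / cfg.bin_width
    return groups.summed_rates(rates)


def estimate_normalization(
    pre_experiment: SpikeFrame,
    groups: GroupSpec | Sequence[Iterable[int]],
    cfg: DecoderConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate per-group (mu, delta) from a pre-experiment segment.

    mu is the mean of the group-summed firing rate over decoder bins;
    delta is the population SD of the same series, floored at
    ``cfg.delta_floor``.  With ``cfg.normalize_on_smoothed`` the SD is
    taken on the moving-average-smoothed series instead (statistics
    then use only fully-populated windows).
    """
    series = _group_sum_series(pre_experiment, groups, cfg)
    if series.shape[0] < 1:
        raise ValueError("pre-experiment segment too short: no full decoder bin")
    if cfg.normalize_on_smoothed:
        k = cfg.smoothing_bins
        if series.shape[0] >= k:
            kernel = np.ones(k) / k
            series = np.stack(
                [np.convolve(series[:, j], kernel, mode="valid") for j in range(4)],
                axis=-1,
            )
    mu = series.mean(axis=0)
    delta = np.maximum(series.std(axis=0), cfg.delta_floor)
    return mu, delta


class Decoder:
    """Stateful decoding pipeline: smooth, group-sum, normalize, rectify, scale.

    Feed it one 100 ms bin of per-channel counts at a time via
    :meth:`step`; it returns the action values and clamped velocity for
    that bin.
    """

    def __init__(self, groups: GroupSpec, cfg: DecoderConfig | None = None,
                 n_channels: int | None = None) -> None:
        if not groups.normalized:
            raise ValueError("GroupSpec must carry mu/delta before decoding")
        self.cfg = cfg or DecoderConfig()
        self.groups = groups
        if n_channels is None:
            n_channels = max(groups.channels) + 1
        self.state = DecoderState(n_channels, self.cfg.smoothing_bins)

    def step(self, new_counts: np.ndarray) -> tuple[ActionValues, CursorVelocity]:
        rates = smooth_firing_rates(self.state, new_counts, self.cfg)
        sums = self.groups.summed_rates(rates)
        a = action_value(sums, self.groups.mu, self.groups.delta, self.cfg.c)
        values = ActionValues(a)
        return values, decode_velocity(values, self.cfg)

    def reset(self) -> None:
        self.state = DecoderState(self.state.n_channels, self.cfg.smoothing_bins)


def step(
    state: DecoderState,
    new_counts: np.ndarray,
    groups: GroupSpec,
    cfg: DecoderConfig,
) -> tuple[ActionValues, CursorVelocity]:
    """Functional form of one decoder step (see :class:`Decoder`)."""
    if not groups.normalized:
        raise ValueError("GroupSpec must carry mu/delta before decoding")
    rates = smooth_firing_rates(state, new_counts, cfg)
    sums = groups.summed_rates(rates)
    a = ActionValues(action_value(sums, groups.mu, groups.delta, cfg.c))
    return a, decode_velocity(a, cfg)
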