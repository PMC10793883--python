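"""Chance-level success rate by shuffled replay.

To ask what success rate would arise if neural activity were
independent of the visual cue, the 10 ms spike bins recorded during
cursor-movement portions of a session are randomly permuted in time
(jointly across channels, so each bin's population vector stays
intact), re-summed into 100 ms decoder bins, and replayed through the
decoder and an offline reconstruction of the task.  Replay trials use
the session's task parameters except that every trial's duration is
fixed at 10 s: failure to reach the target and hold within 10 s is a
failed trial.  Between replay trials the cursor is reset to the center
(variant T) or relocated to the last target's center, as if it had
been reached (variant K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import DecoderConfig, TaskConfig
from .decoder import Decoder, GroupSpec
from .frames import SpikeFrame
from .session_log import SessionLog
from .task import integrate_position, next_target

__all__ = [
    "BaselineResult",
    "shuffle_bins",
    "movement_spike_frame",
    "simulate_baseline",
    "chance_baseline",
]


@dataclass(frozen=True)
class BaselineResult:
    """Shuffled-replay chance rates, per session and averaged."""

    per_session_rate: tuple[float, ...]
    mean_rate: float
    n_trials: int
    seed: int

    def __post_init__(self) -> None:
        if any(not 0 <= r <= 1 for r in self.per_session_rate):
            raise ValueError("rates must lie in [0, 1]")


def shuffle_bins(frame: SpikeFrame, rng: np.random.Generator) -> SpikeFrame:
    """Permute the time order of 10 ms bins, jointly across channels.

    The multiset of per-channel bin counts — indeed each bin's whole
    across-channel vector — is preserved; only the temporal relation
    to task events is destroyed.
    """
    if frame.n_bins < 2:
        raise ValueError("need at least 2 bins to shuffle")
    perm = rng.permutation(frame.n_bins)
    return SpikeFrame(frame.counts[perm], channel_ids=list(frame.channel_ids),
                      bin_width=frame.bin_width)


def movement_spike_frame(log: SessionLog) -> SpikeFrame:
    """10 ms spikes restricted to movement epochs (trials minus freeze)."""
    mask = log.movement_bin_mask()
    factor = int(round(log.decoder_cfg.bin_width / log.spikes.bin_width))
    keep = np.repeat(mask, factor)
    n = min(len(keep), log.spikes.n_bins)
    counts = log.spikes.counts[:n][keep[:n]]
    if counts.shape[0] == 0:
        raise ValueError("session has no movement bins")
    return SpikeFrame(counts, channel_ids=list(log.spikes.channel_ids),
                      bin_width=log.spikes.bin_width)


def simulate_baseline(
    shuffled: SpikeFrame,
    groups: GroupSpec,
    decoder_cfg: DecoderConfig,
    task_cfg: TaskConfig,
    rng: np.random.Generator,
    trial_duration: float = 10.0,
) -> tuple[float, int, int]:
    """Replay shuffled spikes through decoder + offline task.

    Returns (success_rate, n_trials, n_successes).  Trials are clocked
    at exactly ``trial_duration`` on failure; successes end at hold
    completion.  An incomplete final trial (data exhausted) is
    discarded.
    """
    factor = int(round(decoder_cfg.bin_width / shuffled.bin_width))
    binned = shuffled.rebin(factor)
    n_bins = binned.shape[0]
    bins_per_trial = int(round(trial_duration / task_cfg.dt))
    if n_bins < bins_per_trial:
        raise ValueError(
            f"shuffled frame too short for one {trial_duration:.0f} s trial: "
            f"{n_bins} bins < {bins_per_trial}"
        )
    dec = Decoder(groups, decoder_cfg, n_channels=shuffled.n_channels)
    position = (0.0, 0.0)
    prev_record = None
    b = 0
    n_trials = n_success = 0
    while n_bins - b >= 1:
        target, _angle = next_target(task_cfg, prev_record, rng)
        if task_cfg.variant == "T":
            position = (0.0, 0.0)
        # variant K: cursor already relocated to the last target center
        hold = 0.0
        trial_bins = 0
        outcome = None
        while trial_bins < bins_per_trial and b < n_bins:
            _a, v = dec.step(binned[b])
            b += 1
            trial_bins += 1
            position = integrate_position(position, v, task_cfg)
            inside = math.hypot(position[0] - target[0], position[1] - target[1]) \
                <= task_cfg.target_radius
            hold = hold + task_cfg.dt if inside else 0.0
            if hold >= task_cfg.hold_time - 1e-12:
                outcome = "success"
                break
        if outcome is None:
            outcome = "fail" if trial_bins == bins_per_trial else None
        if outcome is None:
            break  # data exhausted mid-trial: discard
        n_trials += 1
        n_success += outcome == "success"
        prev_record = _FakePrev(target)
        if task_cfg.variant == "K":
            position = target  # relocate as if the target had been reached
    if n_trials == 0:
        raise ValueError("no complete replay trial")
    return n_success / n_trials, n_trials, n_success


class _FakePrev:
    """Minimal stand-in with the attribute next_target inspects."""

    def __init__(self, target: tuple[float, float]) -> None:
        self.target_position = target


def chance_baseline(
    logs: list[SessionLog],
    seed: int,
    n_shuffles: int = 1,
    trial_duration: float = 10.0,
) -> BaselineResult:
    """Shuffled-replay baseline for a set of session logs.

    Each session's movement-epoch spikes are shuffled ``n_shuffles``
    times and replayed; the session rate is the mean over shuffles, and
    ``mean_rate`` averages across sessions.
    """
    rng = np.random.default_rng(seed)
    per_session = []
    total_trials = 0
    for log in logs:
        frame = movement_spike_frame(log)
        rates = []
        for _ in range(n_shuffles):
            shuffled = shuffle_bins(frame, rng)
            rate, n_trials, _ns = simulate_baseline(
                shuffled, log.group_spec, log.decoder_cfg, log.task_cfg, rng,
                trial_duration=trial_duration,
            )
            rates.append(rate)
            total_trials += n_trials
        per_session.append(float(np.mean(rates)))
    return BaselineResult(
        per_session_rate=tuple(per_session),
        mean_rate=float(np.mean(per_session)),
        n_trials=total_trials,
        seed=seed,
    )
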