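"""Session-log container and its on-disk format.

A session log bundles everything one closed-loop session produced:

* ``header.json`` — format version, session index, seed, configs, and
  the group spec with its normalization constants;
* ``spikes.csv``  — per-channel spike counts on the 10 ms grid
  (rows = bins, columns = channels);
* ``frames.csv``  — per-100 ms decoded state: action values, velocity,
  cursor position, trial index, freeze flag;
* ``trials.jsonl`` — one JSON object per trial.

Plain-text containers are used throughout so logs are diffable and the
baseline's 10 ms shuffle can be recomputed from the same artifact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import DecoderConfig, TaskConfig, _build_section
from .decoder import GroupSpec
from .frames import SpikeFrame
from .task import TrialRecord

__all__ = ["SessionLog", "SessionLogError", "write_session_log", "read_session_log"]

FORMAT_VERSION = "1"

FRAME_COLUMNS = [
    "bin", "t", "a1", "a2", "a3", "a4", "vx", "vy", "x", "y",
    "trial_index", "frozen",
]


class SessionLogError(ValueError):
    """Schema or consistency violation in a session log."""


@dataclass
class SessionLog:
    """In-memory session log; see module docstring for the layout."""

    session_index: int
    seed: int
    decoder_cfg: DecoderConfig
    task_cfg: TaskConfig
    group_spec: GroupSpec
    spikes: SpikeFrame
    frames: pd.DataFrame
    trials: list[TrialRecord]
    pre_experiment: SpikeFrame | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        missing = set(FRAME_COLUMNS) - set(self.frames.columns)
        if missing:
            raise SessionLogError(f"frames table missing columns: {sorted(missing)}")
        factor = int(round(self.decoder_cfg.bin_width / self.spikes.bin_width))
        if len(self.frames) * factor > self.spikes.n_bins:
            raise SessionLogError(
                "frames extend past the spike matrix: "
                f"{len(self.frames)} frames x {factor} spike bins > {self.spikes.n_bins}"
            )
        if not self.group_spec.normalized:
            raise SessionLogError("group spec lacks normalization constants")
        if max(self.group_spec.channels, default=-1) >= self.spikes.n_channels:
            raise SessionLogError("group spec references channels beyond the spike matrix")
        n = len(self.frames)
        for tr in self.trials:
            if not (0 <= tr.start_bin <= tr.movement_start_bin <= tr.end_bin <= n):
                raise SessionLogError(
                    f"trial {tr.index}: bin range ({tr.start_bin}, {tr.end_bin}) "
                    f"outside frames table of length {n}"
                )

    @property
    def success_rate(self) -> float:
        if not self.trials:
            return float("nan")
        return float(np.mean([t.success for t in self.trials]))

    def trial_action_values(self, trial: TrialRecord) -> np.ndarray:
        """(n_move_bins, 4) action values of a trial's movement phase."""
        sl = self.frames.iloc[trial.movement_start_bin:trial.end_bin]
        return sl[["a1", "a2", "a3", "a4"]].to_numpy()

    def movement_bin_mask(self) -> np.ndarray:
        """Boolean per-frame mask of bins inside trials, excluding freeze."""
        mask = np.zeros(len(self.frames), dtype=bool)
        for tr in self.trials:
            mask[tr.movement_start_bin:tr.end_bin] = True
        return mask


def _trial_to_dict(tr: TrialRecord) -> dict[str, Any]:
    d = dataclasses.asdict(tr)
    d["trajectory"] = np.asarray(tr.trajectory).tolist()
    d["target_position"] = list(tr.target_position)
    d["start_position"] = list(tr.start_position)
    d.pop("action_value_series", None)
    return d


def _trial_from_dict(d: dict[str, Any]) -> TrialRecord:
    return TrialRecord(
        index=int(d["index"]),
        target_position=tuple(d["target_position"]),
        target_angle=float(d["target_angle"]),
        freeze_duration=float(d["freeze_duration"]),
        outcome=str(d["outcome"]),
        movement_duration=float(d["movement_duration"]),
        start_position=tuple(d["start_position"]),
        trajectory=np.asarray(d["trajectory"], dtype=float),
        start_bin=int(d["start_bin"]),
        movement_start_bin=int(d["movement_start_bin"]),
        end_bin=int(d["end_bin"]),
    )


def write_session_log(log: SessionLog, path: str | Path) -> Path:
    """Write a session log as a directory of plain-text files."""
    log.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "format_version": FORMAT_VERSION,
        "session_index": log.session_index,
        "seed": log.seed,
        "decoder": dataclasses.asdict(log.decoder_cfg),
        "task": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in dataclasses.asdict(log.task_cfg).items()
        },
        "group_spec": {
            "groups": [list(g) for g in log.group_spec.groups],
            "mu": log.group_spec.mu.tolist(),
            "delta": log.group_spec.delta.tolist(),
        },
        "spike_bin_width": log.spikes.bin_width,
        "meta": log.meta,
    }
    (path / "header.json").write_text(json.dumps(header, indent=2))
    pd.DataFrame(log.spikes.counts, columns=log.spikes.channel_ids).to_csv(
        path / "spikes.csv", index=False
    )
    log.frames.to_csv(path / "frames.csv", index=False)
    with open(path / "trials.jsonl", "w") as fh:
        for tr in log.trials:
            fh.write(json.dumps(_trial_to_dict(tr)) + "\n")
    if log.pre_experiment is not None:
        pd.DataFrame(
            log.pre_experiment.counts, columns=log.pre_experiment.channel_ids
        ).to_csv(path / "pre_experiment_spikes.csv", index=False)
    return path


def read_session_log(path: str | Path) -> SessionLog:
    """Read and validate a session log written by :func:`write_session_log`."""
    path = Path(path)
    header_path = path / "header.json"
    if not header_path.exists():
        raise SessionLogError(f"{path}: no header.json — not a session log")
    header = json.loads(header_path.read_text())
    version = header.get("format_version")
    if version != FORMAT_VERSION:
        raise SessionLogError(
            f"{path}: unsupported format version {version!r} (expected {FORMAT_VERSION!r})"
        )
    decoder_cfg = _build_section(DecoderConfig, header["decoder"], "decoder")
    task_cfg = _build_section(TaskConfig, header["task"], "task")
    gs = header["group_spec"]
    group_spec = GroupSpec(
        tuple(tuple(g) for g in gs["groups"]),
        mu=np.asarray(gs["mu"], float),
        delta=np.asarray(gs["delta"], float),
    )
    spikes_df = pd.read_csv(path / "spikes.csv")
    spikes = SpikeFrame(
        spikes_df.to_numpy(dtype=np.int64),
        channel_ids=list(spikes_df.columns),
        bin_width=float(header.get("spike_bin_width", 0.01)),
    )
    frames = pd.read_csv(path / "frames.csv")
    trials = []
    with open(path / "trials.jsonl") as fh:
        for line in fh:
            line = line.strip()
            if line:
                trials.append(_trial_from_dict(json.loads(line)))
    pre = None
    pre_path = path / "pre_experiment_spikes.csv"
    if pre_path.exists():
        pre_df = pd.read_csv(pre_path)
        pre = SpikeFrame(
            pre_df.to_numpy(dtype=np.int64),
            channel_ids=list(pre_df.columns),
            bin_width=float(header.get("spike_bin_width", 0.01)),
        )
    log = SessionLog(
        session_index=int(header["session_index"]),
        seed=int(header["seed"]),
        decoder_cfg=decoder_cfg,
        task_cfg=task_cfg,
        group_spec=group_spec,
        spikes=spikes,
        frames=frames,
        trials=trials,
        pre_experiment=pre,
        meta=header.get("meta", {}),
    )
    log.validate()
    return log
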