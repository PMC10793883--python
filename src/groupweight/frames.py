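"""Spike-count container on the 10 ms grid.

The whole pipeline stores spikes at 10 ms resolution even though the
decoder consumes 100 ms bins: the chance-baseline procedure permutes
10 ms bins, so both must be derivable from the same object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeFrame", "SPIKE_BIN_WIDTH"]

#: width of one spike bin, seconds
SPIKE_BIN_WIDTH = 0.01


@dataclass
class SpikeFrame:
    """Per-channel spike counts on a uniform 10 ms grid.

    ``counts`` has shape (n_bins, n_channels) and holds non-negative
    integers.  ``channel_ids`` names the columns.
    """

    counts: np.ndarray
    channel_ids: list[str] = field(default_factory=list)
    bin_width: float = SPIKE_BIN_WIDTH

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (n_bins, n_channels)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("spike counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.counts.shape[1])]
        if len(self.channel_ids) != self.counts.shape[1]:
            raise ValueError("channel_ids length does not match counts columns")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def rebin(self, factor: int) -> np.ndarray:
        """Sum consecutive groups of ``factor`` bins (trailing remainder
        dropped); returns an (n_bins // factor, n_channels) int array."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        n = (self.n_bins // factor) * factor
        return self.counts[:n].reshape(-1, factor, self.n_channels).sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeFrame):
            return NotImplemented
        return (
            self.channel_ids == other.channel_ids
            and self.bin_width == other.bin_width
            and self.counts.shape == other.counts.shape
            and bool(np.all(self.counts == other.counts))
        )
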