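"""Channel-rank transformation.

At every time point the C channel amplitudes are sorted in descending
order and the 1-based channel indices are emitted in that order; the
per-timepoint blocks are concatenated in time order, giving a flat
sequence of length C*N.  Only the relative ordering of channels carries
through, so the transform is invariant to any strictly increasing
rescaling of the amplitudes.

Ties are broken stably: among equal amplitudes the lower channel index
comes first, so a constant column yields 1, 2, ..., C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EegSegment

__all__ = ["RankSequence", "channel_transform"]


@dataclass
class RankSequence:
    """Flat sequence of 1-based channel indices, C per time point."""

    values: np.ndarray
    n_channels: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1:
            raise ValueError("rank sequence must be 1-D")
        c = self.n_channels
        if c < 2:
            raise ValueError("need at least 2 channels")
        if self.values.size % c != 0:
            raise ValueError(
                f"length {self.values.size} is not a multiple of C={c}"
            )
        if self.values.size and (self.values.min() < 1 or self.values.max() > c):
            raise ValueError(f"rank values must lie in 1..{c}")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n_timepoints(self) -> int:
        return self.values.size // self.n_channels

    def blocks(self) -> np.ndarray:
        """View as (N, C): one row of channel indices per time point."""
        return self.values.reshape(self.n_timepoints, self.n_channels)


def channel_transform(segment: EegSegment) -> RankSequence:
    """Rank channels by descending amplitude at each time point.

    Returns a :class:`RankSequence` whose t-th aligned block of C values
    is the permutation of 1..C ordering the channels from largest to
    smallest amplitude at time t (stable: lower index first on ties).
    """
    data = segment.data
    # stable argsort of -x: descending by value, ascending by index on ties
    idx = np.argsort(-data, axis=0, kind="stable") + 1
    return RankSequence(values=idx.ravel(order="F"), n_channels=segment.n_channels)
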