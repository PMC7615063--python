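"""Online data path: 100-ms blocks into a 1-s ring buffer, blink flags.

The acquisition side delivers the combined MEG + gaze + trigger stream in
fixed 100-ms blocks.  The decoder consumes the most recent second, so the
blocks feed a FIFO ring buffer of 1 s capacity that refreshes every block.
Trials containing a blink in the scrutinized span (the whole tagging phase in
training; the last second before the ball collision in the game) are flagged
invalid and excluded from accuracy.

The simulation clock advances in block ticks; there is no wall-clock
coupling, so runs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthmeg import Recording

#: minimum contiguous gaze-gap duration counted as a blink
BLINK_MIN_GAP_S = 0.050


class BufferNotReady(RuntimeError):
    """Raised when a window is requested before the buffer has filled."""


class RingBuffer:
    """Fixed-capacity FIFO over the most recent samples of a multichannel stream.

    ``capacity`` must be an integer multiple of ``block_size``; window queries
    are refused until ``capacity`` samples have been pushed.
    """

    def __init__(self, n_channels: int, capacity: int = 1000, block_size: int = 100):
        if capacity % block_size != 0:
            raise ValueError("capacity must be an integer multiple of block_size")
        self.n_channels = n_channels
        self.capacity = capacity
        self.block_size = block_size
        self._data = np.zeros((n_channels, capacity))
        self._filled = 0  # samples pushed so far, saturating at capacity
        self._pos = 0  # next write position

    @property
    def is_full(self) -> bool:
        return self._filled >= self.capacity

    def push_block(self, block: np.ndarray) -> "RingBuffer":
        block = np.asarray(block, dtype=float)
        if block.shape != (self.n_channels, self.block_size):
            raise ValueError(
                f"expected block of shape ({self.n_channels}, {self.block_size}), "
                f"got {block.shape}"
            )
        self._data[:, self._pos : self._pos + self.block_size] = block
        self._pos = (self._pos + self.block_size) % self.capacity
        self._filled = min(self._filled + self.block_size, self.capacity)
        return self

    def current_window(self) -> np.ndarray:
        """The most recent ``capacity`` samples in chronological order.

        Non-mutating; raises :class:`BufferNotReady` until the buffer fills.
        """
        if not self.is_full:
            raise BufferNotReady(
                f"buffer holds {self._filled}/{self.capacity} samples"
            )
        return np.roll(self._data, -self._pos, axis=1).copy()


def detect_blink(gaze_block: np.ndarray, srate: float = 1000.0) -> bool:
    """True iff a contiguous gaze gap of at least 50 ms occurs in the block.

    Gap samples are NaN sentinels written by the eye tracker (or simulator)
    when the pupil is lost.
    """
    gap = np.isnan(np.asarray(gaze_block, dtype=float))
    if not gap.any():
        return False
    min_run = int(round(BLINK_MIN_GAP_S * srate))
    # run lengths of consecutive gap samples
    padded = np.concatenate([[0], gap.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return bool(np.any(ends - starts >= min_run))


@dataclass(frozen=True)
class ValidityFlag:
    trial_id: int
    valid: bool
    reason: str  # ok | blink_in_tagging | blink_pre_collision


def flag_trial(
    trial_id: int,
    gaze_span: np.ndarray,
    phase: str,
    srate: float = 1000.0,
) -> ValidityFlag:
    """Blink-validity flag for one trial.

    ``gaze_span`` must already be restricted to the scrutinized span: the
    entire 2-s tagging phase for ``phase="training_tagging"``, or the last
    second before the collision for ``phase="game_pre_collision"``.
    """
    if phase not in ("training_tagging", "game_pre_collision"):
        raise ValueError(f"unknown phase {phase!r}")
    blinked = detect_blink(gaze_span, srate)
    if not blinked:
        return ValidityFlag(trial_id, True, "ok")
    reason = (
        "blink_in_tagging" if phase == "training_tagging" else "blink_pre_collision"
    )
    return ValidityFlag(trial_id, False, reason)


def iter_blocks(rec: Recording, block_size: int = 100):
    """Replay a stored recording as consecutive (channels x block_size) blocks.

    Trailing samples that do not fill a whole block are dropped, mirroring the
    block-wise acquisition path.
    """
    n_blocks = rec.n_samples // block_size
    for b in range(n_blocks):
        yield rec.data[:, b * block_size : (b + 1) * block_size]
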