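"""Flicker sequences and patch geometry for rapid invisible frequency tagging (RIFT).

Two patches in the lower visual field are luminance-modulated above the
flicker-fusion threshold -- 56 Hz on the left, 60 Hz on the right -- on a
1440 Hz frame clock.  The flicker is invisible to the observer but drives a
narrowband steady-state response in visual cortex.  This module produces the
frame-indexed luminance sequences and the transparency masks that fade the
patch edges into the background.

Screen coordinates are normalized to [0, 1] x [0, 1] with the origin at the
top-left, x increasing rightward and y downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LEFT_TAG_HZ = 56.0
RIGHT_TAG_HZ = 60.0
FRAME_RATE_HZ = 1440.0


@dataclass(frozen=True)
class FlickerSpec:
    """Luminance flicker of one tagged patch.

    Parameters
    ----------
    tag_frequency : float
        Tagging frequency in Hz (56 for the left patch, 60 for the right).
    frame_rate : float
        Display frame rate in Hz.
    duration : float
        Sequence duration in seconds.
    waveform : {"sinusoidal", "square"}
        Shape of the luminance modulation.  Sinusoidal is the default; its
        spectrum is a single line at ``tag_frequency``.
    depth : float
        Modulation depth as a fraction of full luminance, in [0, 1].
        ``depth=0`` yields constant mid-grey (no flicker).
    """

    tag_frequency: float = LEFT_TAG_HZ
    frame_rate: float = FRAME_RATE_HZ
    duration: float = 1.0
    waveform: str = "sinusoidal"
    depth: float = 1.0

    def __post_init__(self) -> None:
        if self.tag_frequency >= self.frame_rate / 2:
            raise ValueError(
                f"tag_frequency {self.tag_frequency} Hz aliases at frame rate "
                f"{self.frame_rate} Hz (Nyquist {self.frame_rate / 2} Hz)"
            )
        if self.tag_frequency <= 0:
            raise ValueError("tag_frequency must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("depth must lie in [0, 1]")
        if self.waveform not in ("sinusoidal", "square"):
            raise ValueError(f"unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class PatchSpec:
    """Geometry of one tagged patch in normalized screen units.

    The patch edges are fully transparent and ramp linearly to full opacity
    over ``fade_fraction`` of the patch width/height, so the patch blends into
    the background texture without a sharp (visible) border.
    """

    width: float = 0.4
    height: float = 0.4
    fade_fraction: float = 0.10
    side: str = "left"

    def __post_init__(self) -> None:
        if not 0.0 < self.fade_fraction < 0.5:
            raise ValueError("fade_fraction must lie in (0, 0.5)")
        if not (0.0 < self.width <= 1.0 and 0.0 < self.height <= 1.0):
            raise ValueError("width and height must lie in (0, 1]")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


def luminance_sequence(spec: FlickerSpec) -> np.ndarray:
    """Frame-indexed luminance values in [0, 1] for one flicker spec.

    The continuous modulation is sampled at frame times ``k / frame_rate``;
    frequencies that do not divide the frame rate (56 Hz at 1440 Hz gives
    25.714 frames per cycle) are therefore represented without forcing integer
    cycles, at the cost of negligible spectral leakage over 1-s windows.

    For the square wave the frame is "high" during the first half of each
    flicker cycle, which at 60 Hz / 1440 Hz yields exactly 12 high and 12 low
    frames per 24-frame cycle.
    """
    n_frames = int(round(spec.frame_rate * spec.duration))
    t = np.arange(n_frames) / spec.frame_rate
    phase = spec.tag_frequency * t  # in cycles
    if spec.waveform == "sinusoidal":
        mod = np.sin(2 * np.pi * phase)
    else:  # square
        mod = np.where(np.mod(phase, 1.0) < 0.5, 1.0, -1.0)
    return 0.5 + 0.5 * spec.depth * mod


def sequence_to_frame(seq: np.ndarray, frame_rate: float = FRAME_RATE_HZ) -> pd.DataFrame:
    """Tabulate a luminance sequence as (frame_index, time_s, luminance)."""
    idx = np.arange(len(seq))
    return pd.DataFrame(
        {"frame_index": idx, "time_s": idx / frame_rate, "luminance": seq}
    )


def export_sequence_csv(seq: np.ndarray, path, frame_rate: float = FRAME_RATE_HZ) -> None:
    """Write a luminance sequence to CSV for inspection."""
    sequence_to_frame(seq, frame_rate).to_csv(path, index=False)


def _edge_ramp(n: int, fade_fraction: float) -> np.ndarray:
    """Linear 0->1 opacity ramp from both edges over ``fade_fraction`` of ``n``."""
    fade_len = fade_fraction * n
    d = np.minimum(np.arange(n), n - 1 - np.arange(n))
    return np.clip(d / fade_len, 0.0, 1.0)


def patch_alpha_mask(spec: PatchSpec, grid_w: int, grid_h: int) -> np.ndarray:
    """2-D opacity mask (grid_h x grid_w) in [0, 1] for a tagged patch.

    Boundary cells are fully transparent (opacity 0); the interior outside the
    fade bands is fully opaque (opacity 1); opacity rises monotonically moving
    inward across a fade band.  The left and right patches are mirror images
    of each other.
    """
    if grid_w < 10 or grid_h < 10:
        raise ValueError("grid dimensions must be >= 10")
    ramp_x = _edge_ramp(grid_w, spec.fade_fraction)
    ramp_y = _edge_ramp(grid_h, spec.fade_fraction)
    mask = np.minimum.outer(ramp_y, ramp_x)
    if spec.side == "right":
        mask = mask[:, ::-1]
    return mask


def background_texture(
    grid_w: int, grid_h: int, seed: int = 0, contrast: float = 0.2
) -> np.ndarray:
    """Static grainy background texture in [0, 1].

    Purely decorative: in the real display it hides the tagged patches.  It is
    static, so it contributes nothing to the tagging spectrum.
    """
    rng = np.random.default_rng(seed)
    return 0.5 + contrast * (rng.random((grid_h, grid_w)) - 0.5)
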