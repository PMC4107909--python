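"""In-memory representation of a time-lapse fluorescence movie."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Movie:
    """A T x H x W fluorescence stack with a uniform frame timebase.

    Parameters
    ----------
    data
        Stack of shape ``(n_frames, height, width)``; stored as float32.
    frame_interval
        Seconds between consecutive frames.
    """

    data: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3-D (T, H, W), got shape {self.data.shape}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def duration(self) -> float:
        """Total covered time in seconds."""
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval
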