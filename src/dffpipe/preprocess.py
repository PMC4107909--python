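"""Rigid registration of every frame to the first frame.

Integer-pixel translation maximizing the FFT cross-correlation with frame 0.
The shift search is bounded to +/-10% of each image dimension to prevent
pathological matches; out-of-frame pixels are filled with the frame median.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .movie import Movie


@dataclass
class FrameShifts:
    """Per-frame (dy, dx) displacement relative to frame 0.

    ``shifts[k]`` is the measured movement of frame k; registration applies
    the inverse translation. ``degenerate[k]`` flags frames where correlation
    was undefined (all-constant frame) and the shift defaulted to (0, 0).
    """

    shifts: np.ndarray  # (n_frames, 2) int
    degenerate: np.ndarray  # (n_frames,) bool

    def __len__(self) -> int:
        return len(self.shifts)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "frame": np.arange(len(self.shifts)),
                "dy": self.shifts[:, 0],
                "dx": self.shifts[:, 1],
                "degenerate": self.degenerate.astype(int),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrameShifts":
        df = pd.read_csv(path)
        return cls(
            shifts=df[["dy", "dx"]].to_numpy(dtype=int),
            degenerate=df["degenerate"].to_numpy(dtype=bool),
        )


def translate_frame(img: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    """Shift image content by (dy, dx), filling uncovered pixels."""
    out = np.full_like(img, fill)
    h, w = img.shape
    ys0, ys1 = max(0, -dy), min(h, h - dy)
    xs0, xs1 = max(0, -dx), min(w, w - dx)
    if ys1 <= ys0 or xs1 <= xs0:
        return out
    out[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx] = img[ys0:ys1, xs0:xs1]
    return out


def _wrapped_indices(n: int, max_shift: int) -> tuple[np.ndarray, np.ndarray]:
    """Index positions of the correlation map covering shifts in
    [-max_shift, max_shift], and the shift value each position encodes."""
    pos = np.concatenate([np.arange(0, max_shift + 1), np.arange(n - max_shift, n)])
    vals = np.where(pos <= n // 2, pos, pos - n)
    return pos, vals


def register_frames(movie: Movie, max_shift_fraction: float = 0.10) -> tuple[Movie, FrameShifts]:
    """Register a movie to its first frame.

    Returns the registered movie (same shape, same frame count) and the
    measured per-frame shifts.
    """
    data = movie.data
    t_n, h, w = data.shape
    if t_n < 2:
        raise ValueError("registration requires at least 2 frames")
    my = max(1, int(round(h * max_shift_fraction)))
    mx = max(1, int(round(w * max_shift_fraction)))
    rows, row_vals = _wrapped_indices(h, my)
    cols, col_vals = _wrapped_indices(w, mx)

    shifts = np.zeros((t_n, 2), dtype=int)
    degenerate = np.zeros(t_n, dtype=bool)
    out = np.empty_like(data)
    out[0] = data[0]

    ref = data[0].astype(np.float64)
    ref_flat = float(ref.std()) == 0.0
    if not ref_flat:
        ref_fft = np.fft.rfft2(ref - ref.mean())

    for t in range(1, t_n):
        frame = data[t].astype(np.float64)
        if ref_flat or float(frame.std()) == 0.0:
            degenerate[t] = True
            out[t] = data[t]
            continue
        cc = np.fft.irfft2(np.fft.rfft2(frame - frame.mean()) * np.conj(ref_fft), s=(h, w))
        sub = cc[np.ix_(rows, cols)]
        i, j = np.unravel_index(int(np.argmax(sub)), sub.shape)
        dy, dx = int(row_vals[i]), int(col_vals[j])
        shifts[t] = (dy, dx)
        if dy == 0 and dx == 0:
            out[t] = data[t]
        else:
            fill = float(np.median(frame))
            out[t] = translate_frame(data[t], -dy, -dx, fill)

    registered = Movie(data=out, frame_interval=movie.frame_interval)
    return registered, FrameShifts(shifts=shifts, degenerate=degenerate)
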