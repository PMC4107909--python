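"""Per-ROI temporal profiles: baseline (photobleaching) fitting, peak
detection, and dF/F responder calls.

The baseline model family is exponential-with-fallbacks: a single exponential
is fit by least squares to frames outside response windows; if the fit fails
or the time constant is implausibly long, a linear model is tried, then a
constant (median). dF/F is (peak - baseline at peak frame) / baseline at peak
frame; a cell is a responder when dF/F >= the response threshold (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from .movie import Movie
from .roi import ROI
from .stimuli import StimulusEvent, StimulusSchedule

RESPONSE_THRESHOLD = 0.30  # dF/F responder threshold
DEFAULT_RESPONSE_WINDOW_S = 60.0


@dataclass
class Trace:
    """Raw temporal profile of one ROI (per-frame mean over its pixels)."""

    values: np.ndarray
    frame_interval: float
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("trace values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class BaselineModel:
    """Fitted baseline: exponential (B0, tau), linear (intercept, slope)
    or constant (level). ``fitted_on`` is the frame mask used for the fit."""

    model_kind: str  # "exponential" | "linear" | "constant"
    parameters: tuple[float, ...]
    fitted_on: np.ndarray | None = None

    def predict(self, times: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(times, dtype=np.float64)
        if self.model_kind == "exponential":
            b0, tau = self.parameters
            out = b0 * np.exp(-t / tau)
        elif self.model_kind == "linear":
            intercept, slope = self.parameters
            out = intercept + slope * t
        elif self.model_kind == "constant":
            (level,) = self.parameters
            out = np.full_like(t, level, dtype=np.float64)
        else:  # pragma: no cover
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        return float(out) if np.isscalar(times) else out


@dataclass
class ResponseCall:
    """Per (ROI, stimulus) quantification and responder flag."""

    roi_id: str
    stimulus: str
    concentration: float | None
    peak_value: float
    peak_frame: int
    baseline_at_peak: float
    delta_f_over_f: float
    responder: bool


def extract_trace(movie: Movie, roi: ROI) -> Trace:
    """Per-frame mean fluorescence over the ROI's pixel set."""
    px = roi.pixels
    if len(px) == 0:
        raise ValueError("cannot extract a trace from an empty ROI")
    h, w = movie.frame_shape
    if px[:, 0].max() >= h or px[:, 1].max() >= w or px.min() < 0:
        raise ValueError("ROI pixels fall outside the movie frame")
    values = movie.data[:, px[:, 0], px[:, 1]].mean(axis=1, dtype=np.float64)
    return Trace(values=values, frame_interval=movie.frame_interval, roi_id=roi.roi_id)


def response_window_mask(
    schedule: StimulusSchedule,
    n_frames: int,
    frame_interval: float,
    response_window_s: float = DEFAULT_RESPONSE_WINDOW_S,
) -> np.ndarray:
    """Boolean mask of frames inside any response window
    [onset, onset + response_window)."""
    w = int(round(response_window_s / frame_interval))
    mask = np.zeros(n_frames, dtype=bool)
    for ev in schedule:
        mask[ev.onset_frame : min(n_frames, ev.onset_frame + w)] = True
    return mask


def fit_baseline(
    trace: Trace,
    schedule: StimulusSchedule,
    response_window_s: float = DEFAULT_RESPONSE_WINDOW_S,
) -> BaselineModel:
    """Fit the photobleaching baseline to frames outside response windows."""
    in_response = response_window_mask(
        schedule, trace.n_frames, trace.frame_interval, response_window_s
    )
    free = ~in_response
    if int(free.sum()) < 10:
        raise ValueError(
            f"baseline fit needs >= 10 frames outside response windows, got {int(free.sum())}"
        )
    t = trace.times[free]
    y = trace.values[free]
    duration = trace.times[-1] if trace.n_frames > 1 else trace.frame_interval

    if float(np.ptp(y)) == 0.0:
        return BaselineModel("constant", (float(y[0]),), fitted_on=free)

    model = _fit_exponential(t, y, duration)
    if model is not None:
        model.fitted_on = free
        return model

    # linear fallback; must stay strictly positive over the whole trace
    slope, intercept = np.polyfit(t, y, 1)
    pred = intercept + slope * trace.times
    if np.all(pred > 0):
        return BaselineModel("linear", (float(intercept), float(slope)), fitted_on=free)
    return BaselineModel("constant", (float(np.median(y)),), fitted_on=free)


def _fit_exponential(t: np.ndarray, y: np.ndarray, duration: float) -> BaselineModel | None:
    if np.all(y > 0):
        # log-linear seed: exact for clean exponentials
        s, i = np.polyfit(t, np.log(y), 1)
        tau0 = -1.0 / s if s < -1e-12 else 10.0 * duration
        b0_0 = float(np.exp(i))
    else:
        tau0 = duration
        b0_0 = max(float(np.median(y)), 1e-6)
    tau0 = min(max(tau0, 1e-6), 1e5 * duration)
    try:
        popt, _ = curve_fit(
            lambda tt, b0, tau: b0 * np.exp(-tt / tau),
            t,
            y,
            p0=(b0_0, tau0),
            bounds=([1e-12, 1e-12], [np.inf, 1e6 * duration]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return None
    b0, tau = float(popt[0]), float(popt[1])
    if not np.isfinite(tau) or tau > 100.0 * duration or b0 <= 0:
        return None
    with np.errstate(under="ignore"):
        end = b0 * np.exp(-duration / tau)
    if not np.isfinite(end) or end <= 0:  # degenerate fit underflowing to zero
        return None
    return BaselineModel("exponential", (b0, tau))


def detect_peak(
    trace: Trace,
    baseline: BaselineModel,
    event: StimulusEvent,
    response_window_s: float = DEFAULT_RESPONSE_WINDOW_S,
) -> tuple[float, int]:
    """Maximum of a 3-frame moving average over [onset, onset + window).

    Returns ``(peak_value, peak_frame)`` where ``peak_frame`` is the center
    frame of the maximizing 3-frame window.
    """
    w0 = event.onset_frame
    w1 = w0 + int(round(response_window_s / trace.frame_interval))
    if w1 > trace.n_frames:
        raise ValueError("response window extends beyond the trace")
    if w1 - w0 < 3:
        raise ValueError("response window must span at least 3 frames")
    smoothed = uniform_filter1d(trace.values, size=3, mode="nearest")
    peak_frame = w0 + int(np.argmax(smoothed[w0:w1]))
    return float(smoothed[peak_frame]), peak_frame


def call_response(
    trace: Trace,
    baseline: BaselineModel,
    event: StimulusEvent,
    response_window_s: float = DEFAULT_RESPONSE_WINDOW_S,
    response_threshold: float = RESPONSE_THRESHOLD,
) -> ResponseCall:
    """dF/F at the detected peak, baseline evaluated at the peak frame."""
    peak_value, peak_frame = detect_peak(trace, baseline, event, response_window_s)
    b = float(baseline.predict(peak_frame * trace.frame_interval))
    if b <= 0:
        raise ValueError(f"baseline at peak frame {peak_frame} is non-positive ({b:g})")
    dff = (peak_value - b) / b
    return ResponseCall(
        roi_id=trace.roi_id,
        stimulus=event.label,
        concentration=event.concentration,
        peak_value=peak_value,
        peak_frame=peak_frame,
        baseline_at_peak=b,
        delta_f_over_f=dff,
        responder=bool(dff >= response_threshold),
    )
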