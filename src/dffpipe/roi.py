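"""ROI detection: per-stimulus (local) candidates by a signal-to-noise score,
shape-based filtering, and integration into a global ROI list."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .movie import Movie
from .stimuli import StimulusEvent

GLOBAL_SOURCE = "global"


@dataclass
class DetectionParams:
    """Detection and merge thresholds; all comparisons are inclusive."""

    snr_threshold: float = 5.0
    min_area: int = 15
    max_area: int = 5000
    min_circularity: float = 0.5
    iou_merge_threshold: float = 0.3
    baseline_window_s: float = 30.0  # pre-onset window used for the SNR score

    def validate(self) -> None:
        if not (0 < self.min_area < self.max_area):
            raise ValueError("require 0 < min_area < max_area")
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be positive")
        if not (0.0 <= self.min_circularity <= 1.0):
            raise ValueError("min_circularity must be in [0, 1]")
        if not (0.0 <= self.iou_merge_threshold <= 1.0):
            raise ValueError("iou_merge_threshold must be in [0, 1]")


@dataclass
class ROI:
    """A connected pixel set, local (per-stimulus) or global (integrated)."""

    pixels: np.ndarray  # (n, 2) int, (row, col), lexicographically sorted
    source_stimulus: str  # stimulus label, or "global"
    sources: tuple[str, ...] = ()  # contributing stimuli for global ROIs
    roi_id: str = ""
    _pixel_set: frozenset = field(default=None, repr=False, compare=False, init=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=int)
        if px.ndim != 2 or px.shape[1] != 2 or len(px) == 0:
            raise ValueError("pixels must be a non-empty (n, 2) array")
        order = np.lexsort((px[:, 1], px[:, 0]))
        self.pixels = px[order]
        if not self.sources and self.source_stimulus != GLOBAL_SOURCE:
            self.sources = (self.source_stimulus,)

    @property
    def pixel_set(self) -> frozenset:
        if self._pixel_set is None:
            self._pixel_set = frozenset(map(tuple, self.pixels.tolist()))
        return self._pixel_set

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean())


def circularity(roi: ROI) -> float:
    """Isoperimetric ratio 4*pi*area / perimeter**2 of the pixel set."""
    px = roi.pixels
    r0, c0 = px[:, 0].min(), px[:, 1].min()
    mask = np.zeros((px[:, 0].max() - r0 + 3, px[:, 1].max() - c0 + 3), dtype=np.uint8)
    mask[px[:, 0] - r0 + 1, px[:, 1] - c0 + 1] = 1
    props = regionprops(mask)[0]
    if props.perimeter == 0:  # single pixel / degenerate: treat as round
        return 1.0
    return 4.0 * math.pi * roi.area / props.perimeter**2


def iou(a: ROI, b: ROI) -> float:
    """Intersection-over-union of two pixel sets."""
    sa, sb = a.pixel_set, b.pixel_set
    inter = len(sa & sb)
    if inter == 0:
        return 0.0
    return inter / len(sa | sb)


def detect_local_rois(
    movie: Movie, event: StimulusEvent, params: DetectionParams
) -> list[ROI]:
    """Threshold a per-pixel SNR score over the event window.

    Score = (mean over the event window - mean over the pre-event baseline
    window) / robust SD of the linearly detrended pre-event residuals.
    Pixels scoring >= ``snr_threshold`` form 8-connected candidate ROIs.
    """
    params.validate()
    data = movie.data
    on, off = event.onset_frame, event.offset_frame
    if off > movie.n_frames:
        raise ValueError("event window extends beyond the movie")
    if off - on < 3:
        raise ValueError("event window must span at least 3 frames")
    n_pre = int(round(params.baseline_window_s / movie.frame_interval))
    pre = data[max(0, on - n_pre) : on].astype(np.float64)
    if pre.shape[0] < 3:
        raise ValueError("need at least 3 pre-event frames for the baseline window")

    pre_mean = pre.mean(axis=0)
    # robust SD of residuals about a per-pixel linear trend of the pre window
    t = np.arange(pre.shape[0], dtype=np.float64)
    t_c = t - t.mean()
    slope = np.tensordot(t_c, pre, axes=(0, 0)) / (t_c**2).sum()
    resid = pre - (pre_mean[None] + t_c[:, None, None] * slope[None])
    med = np.median(resid, axis=0)
    robust_sd = 1.4826 * np.median(np.abs(resid - med[None]), axis=0)
    floor = 1e-9 + 1e-3 * np.abs(pre_mean)
    denom = np.maximum(robust_sd, floor)

    win_mean = data[on:off].mean(axis=0, dtype=np.float64)
    score = (win_mean - pre_mean) / denom
    mask = score >= params.snr_threshold

    labeled = cc_label(mask, connectivity=2)
    rois = []
    for lab in range(1, labeled.max() + 1):
        rr, cc = np.nonzero(labeled == lab)
        rois.append(ROI(pixels=np.column_stack([rr, cc]), source_stimulus=event.label))
    return rois


def filter_candidates(rois: list[ROI], params: DetectionParams) -> list[ROI]:
    """Area and circularity gates replacing the original manual inspection."""
    params.validate()
    kept = []
    for roi in rois:
        if not (params.min_area <= roi.area <= params.max_area):
            continue
        if circularity(roi) < params.min_circularity:
            continue
        kept.append(roi)
    return kept


def merge_to_global(
    local_sets: list[tuple[str, list[ROI]]], params: DetectionParams
) -> list[ROI]:
    """Union ROIs across stimuli whose pairwise IoU >= threshold (transitive
    closure). Each global ROI records its contributing stimuli."""
    params.validate()
    items: list[tuple[str, ROI]] = []
    for stim, rois in local_sets:
        for roi in rois:
            items.append((stim, roi))
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    cents = np.array([items[i][1].centroid for i in range(n)]) if n else np.zeros((0, 2))
    reach = np.array([math.sqrt(items[i][1].area) for i in range(n)])
    for i in range(n):
        for j in range(i + 1, n):
            # disjoint bounding circles cannot overlap; skip the set ops
            d = math.hypot(cents[i, 0] - cents[j, 0], cents[i, 1] - cents[j, 1])
            if d > reach[i] + reach[j]:
                continue
            if iou(items[i][1], items[j][1]) >= params.iou_merge_threshold:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged = []
    for members in groups.values():
        pixel_union = set()
        sources = set()
        for i in members:
            stim, roi = items[i]
            pixel_union |= roi.pixel_set
            sources.add(stim)
        merged.append(
            ROI(
                pixels=np.array(sorted(pixel_union)),
                source_stimulus=GLOBAL_SOURCE,
                sources=tuple(sorted(sources)),
            )
        )
    merged.sort(key=lambda r: r.centroid)
    for k, roi in enumerate(merged):
        roi.roi_id = f"roi{k:04d}"
    return merged
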