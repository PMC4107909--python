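"""Population summaries over the ROI x stimulus response matrix: overlap
(Venn) statistics, percent responding, normalized tuning panels, dose-response
curves and co-label gating."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .roi import ROI
from .traces import ResponseCall

StimKey = tuple[str, float | None]


def _as_label_set(stim: str | Iterable[str]) -> set[str]:
    if isinstance(stim, str):
        return {stim}
    return set(stim)


class ResponseMatrix:
    """ROIs x stimuli table of :class:`ResponseCall` records.

    One call per (ROI, stimulus) pair. Optional per-ROI metadata: slice id
    and co-label flag.
    """

    def __init__(
        self,
        calls: Sequence[ResponseCall],
        colabel: dict[str, bool] | None = None,
        slice_of_roi: dict[str, str] | None = None,
    ):
        self._calls: dict[tuple[str, StimKey], ResponseCall] = {}
        self.roi_ids: list[str] = []
        self.stimuli: list[StimKey] = []
        for c in calls:
            key = (c.roi_id, (c.stimulus, c.concentration))
            if key in self._calls:
                raise ValueError(f"duplicate call for ROI {c.roi_id!r}, stimulus {key[1]}")
            self._calls[key] = c
            if c.roi_id not in self.roi_ids:
                self.roi_ids.append(c.roi_id)
            if key[1] not in self.stimuli:
                self.stimuli.append(key[1])
        self.colabel = colabel or {}
        self.slice_of_roi = slice_of_roi or {}

    def __len__(self) -> int:
        return len(self._calls)

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab, _ in self.stimuli:
            if lab not in seen:
                seen.append(lab)
        return seen

    def call(self, roi_id: str, stim: StimKey) -> ResponseCall | None:
        return self._calls.get((roi_id, stim))

    def calls_for_roi(self, roi_id: str) -> list[ResponseCall]:
        return [self._calls[(roi_id, s)] for s in self.stimuli if (roi_id, s) in self._calls]

    def dff(self, roi_id: str, label: str) -> float | None:
        """Max dF/F over all events sharing this label; None if no call."""
        vals = [
            c.delta_f_over_f
            for (rid, (lab, _)), c in self._calls.items()
            if rid == roi_id and lab == label
        ]
        return max(vals) if vals else None

    def responders(self, stim: str | Iterable[str]) -> set[str]:
        """ROIs called responder to any stimulus whose label is in ``stim``."""
        labels = _as_label_set(stim)
        missing = labels - set(self.labels)
        if missing:
            raise KeyError(f"stimuli not present in matrix: {sorted(missing)}")
        return {
            rid
            for (rid, (lab, _)), c in self._calls.items()
            if lab in labels and c.responder
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (rid, (lab, conc)), c in self._calls.items():
            rows.append(
                {
                    "roi_id": rid,
                    "stimulus": lab,
                    "concentration_M": np.nan if conc is None else conc,
                    "peak_value": c.peak_value,
                    "peak_frame": c.peak_frame,
                    "baseline_at_peak": c.baseline_at_peak,
                    "dff": c.delta_f_over_f,
                    "responder": c.responder,
                    "slice_id": self.slice_of_roi.get(rid, ""),
                    "colabel": self.colabel.get(rid, np.nan),
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseMatrix":
        calls = []
        colabel: dict[str, bool] = {}
        slice_of: dict[str, str] = {}
        for row in df.itertuples(index=False):
            conc = None if pd.isna(row.concentration_M) else float(row.concentration_M)
            calls.append(
                ResponseCall(
                    roi_id=str(row.roi_id),
                    stimulus=str(row.stimulus),
                    concentration=conc,
                    peak_value=float(row.peak_value),
                    peak_frame=int(row.peak_frame),
                    baseline_at_peak=float(row.baseline_at_peak),
                    delta_f_over_f=float(row.dff),
                    responder=bool(row.responder),
                )
            )
            if hasattr(row, "colabel") and not pd.isna(row.colabel):
                colabel[str(row.roi_id)] = bool(row.colabel)
            if hasattr(row, "slice_id") and isinstance(row.slice_id, str) and row.slice_id:
                slice_of[str(row.roi_id)] = row.slice_id
        return cls(calls, colabel=colabel or None, slice_of_roi=slice_of or None)

    @classmethod
    def concat(
        cls, matrices: Sequence["ResponseMatrix"], slice_ids: Sequence[str] | None = None
    ) -> "ResponseMatrix":
        """Pool slices; ROI ids are prefixed with their slice id."""
        if slice_ids is None:
            slice_ids = [f"s{k}" for k in range(len(matrices))]
        calls = []
        colabel: dict[str, bool] = {}
        slice_of: dict[str, str] = {}
        for sid, m in zip(slice_ids, matrices):
            for key, c in m._calls.items():
                rid = f"{sid}/{c.roi_id}"
                calls.append(
                    ResponseCall(
                        roi_id=rid,
                        stimulus=c.stimulus,
                        concentration=c.concentration,
                        peak_value=c.peak_value,
                        peak_frame=c.peak_frame,
                        baseline_at_peak=c.baseline_at_peak,
                        delta_f_over_f=c.delta_f_over_f,
                        responder=c.responder,
                    )
                )
            for old_rid, flag in m.colabel.items():
                colabel[f"{sid}/{old_rid}"] = flag
            for old_rid in m.roi_ids:
                slice_of[f"{sid}/{old_rid}"] = sid
        return cls(calls, colabel=colabel or None, slice_of_roi=slice_of)


@dataclass
class VennSummary:
    """Overlap between responder sets A and B."""

    n_a: int
    n_b: int
    n_ab: int
    n_total: int
    pct_b_given_a: float | None  # 100 * n_ab / n_a; None when n_a == 0

    @property
    def undefined(self) -> bool:
        return self.pct_b_given_a is None

    def table(self) -> dict[str, int]:
        """2x2 responder-A x responder-B counts over all ROIs."""
        return {
            "both": self.n_ab,
            "a_only": self.n_a - self.n_ab,
            "b_only": self.n_b - self.n_ab,
            "neither": self.n_total - self.n_a - self.n_b + self.n_ab,
        }


@dataclass
class DoseResponseCurve:
    concentrations: np.ndarray  # strictly increasing, molar
    fraction_responding: np.ndarray
    mean_dff: np.ndarray
    n_cells: int
    threshold_concentration: float | None  # lowest tested conc with a responder
    ec50: float | None = None
    hill_coefficient: float | None = None


@dataclass
class TuningPanel:
    """Per-stimulus mean +/- SEM of per-cell max-normalized dF/F."""

    stimuli: list[str]
    mean: np.ndarray
    sem: np.ndarray
    n_cells: int
    n_excluded: int  # cells whose panel max was <= 0


def overlap_summary(
    matrix: ResponseMatrix, stim_a: str | Iterable[str], stim_b: str | Iterable[str]
) -> VennSummary:
    """Counts of cells responding to A, to B, and to both; a cell is in a set
    if it responds to any member stimulus (any-responder semantics)."""
    set_a = matrix.responders(stim_a)
    set_b = matrix.responders(stim_b)
    n_a, n_b = len(set_a), len(set_b)
    n_ab = len(set_a & set_b)
    pct = 100.0 * n_ab / n_a if n_a > 0 else None
    return VennSummary(n_a=n_a, n_b=n_b, n_ab=n_ab, n_total=len(matrix.roi_ids), pct_b_given_a=pct)


def percent_responding(
    matrix: ResponseMatrix, stim: str, denominator: str = "all_rois"
) -> float:
    """100 x responders / denominator size."""
    if denominator == "all_rois":
        denom = list(matrix.roi_ids)
    elif denominator == "colabel_positive":
        denom = [r for r in matrix.roi_ids if matrix.colabel.get(r, False)]
    else:
        raise ValueError("denominator must be 'all_rois' or 'colabel_positive'")
    if not denom:
        raise ValueError(f"empty denominator ({denominator})")
    resp = matrix.responders(stim)
    return 100.0 * sum(1 for r in denom if r in resp) / len(denom)


def normalized_amplitudes(matrix: ResponseMatrix, panel: Sequence[str]) -> TuningPanel:
    """Each cell's dF/F vector over the panel divided by its own maximum;
    per-stimulus mean and SEM over cells. Cells with max <= 0 are excluded
    (and counted); cells lacking a call for any panel stimulus are skipped."""
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    vectors = []
    n_excluded = 0
    for rid in matrix.roi_ids:
        vals = [matrix.dff(rid, lab) for lab in panel]
        if any(v is None for v in vals):
            continue
        v = np.asarray(vals, dtype=float)
        vmax = v.max()
        if vmax <= 0:
            n_excluded += 1
            continue
        vectors.append(v / vmax)
    if not vectors:
        nan = np.full(len(panel), np.nan)
        return TuningPanel(stimuli=panel, mean=nan, sem=nan.copy(), n_cells=0, n_excluded=n_excluded)
    arr = np.vstack(vectors)
    mean = arr.mean(axis=0)
    if arr.shape[0] > 1:
        sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    else:
        sem = np.full(len(panel), np.nan)
    return TuningPanel(stimuli=panel, mean=mean, sem=sem, n_cells=arr.shape[0], n_excluded=n_excluded)


def dose_response(
    matrix: ResponseMatrix,
    stim: str,
    cell_set: Sequence[str] | None = None,
    fit_hill: bool = True,
    min_fraction: float | None = None,
) -> DoseResponseCurve:
    """Fraction responding and mean dF/F per concentration for a fixed cell
    set, the threshold concentration, and an optional 2-parameter Hill fit.

    ``threshold_concentration`` uses >=1 responder ("as low as" semantics) by
    default; pass ``min_fraction`` for a fraction-based criterion.
    """
    concs = sorted(
        {c for (lab, c) in matrix.stimuli if lab == stim and c is not None}
    )
    if not concs:
        raise KeyError(f"no concentration series for stimulus {stim!r}")
    cells = list(cell_set) if cell_set is not None else list(matrix.roi_ids)
    if not cells:
        raise ValueError("cell_set must be non-empty")
    fractions = np.zeros(len(concs))
    mean_dff = np.zeros(len(concs))
    for k, c in enumerate(concs):
        calls = []
        for rid in cells:
            call = matrix.call(rid, (stim, c))
            if call is None:
                raise ValueError(f"missing call for cell {rid!r} at {c:g} M")
            calls.append(call)
        fractions[k] = np.mean([cl.responder for cl in calls])
        mean_dff[k] = np.mean([cl.delta_f_over_f for cl in calls])

    threshold = None
    for k, c in enumerate(concs):
        hit = fractions[k] >= min_fraction if min_fraction is not None else fractions[k] > 0
        if hit:
            threshold = c
            break

    ec50 = hill = None
    if fit_hill and len(concs) >= 2 and mean_dff.max() > 0:
        ec50, hill = _fit_hill(np.asarray(concs), mean_dff)
    return DoseResponseCurve(
        concentrations=np.asarray(concs),
        fraction_responding=fractions,
        mean_dff=mean_dff,
        n_cells=len(cells),
        threshold_concentration=threshold,
        ec50=ec50,
        hill_coefficient=hill,
    )


def _fit_hill(concs: np.ndarray, mean_dff: np.ndarray) -> tuple[float | None, float | None]:
    """Least-squares Hill fit with the plateau pinned to the max observed
    mean dF/F; free parameters are log10(EC50) and the coefficient."""
    ymax = float(mean_dff.max())
    logc = np.log10(concs)

    def f(lc, lec50, h):
        return ymax / (1.0 + 10.0 ** (h * (lec50 - lc)))

    half = np.argmin(np.abs(mean_dff - ymax / 2.0))
    try:
        popt, _ = curve_fit(
            f,
            logc,
            mean_dff,
            p0=(float(logc[half]), 1.0),
            bounds=([logc.min() - 3.0, 0.05], [logc.max() + 3.0, 10.0]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return None, None
    return float(10.0 ** popt[0]), float(popt[1])


def colabel_gate(
    rois: Sequence[ROI], colabel_image: np.ndarray, intensity_threshold: float
) -> np.ndarray:
    """Boolean mask: ROI is co-label positive iff its mean intensity in the
    second-channel image is >= the threshold."""
    img = np.asarray(colabel_image)
    if img.ndim != 2:
        raise ValueError("colabel image must be 2-D")
    out = np.zeros(len(rois), dtype=bool)
    for i, roi in enumerate(rois):
        px = roi.pixels
        if px[:, 0].max() >= img.shape[0] or px[:, 1].max() >= img.shape[1]:
            raise ValueError("colabel image shape does not match the movie frames")
        out[i] = img[px[:, 0], px[:, 1]].mean() >= intensity_threshold
    return out
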