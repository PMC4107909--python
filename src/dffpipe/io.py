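"""Readers and writers for movies (TIFF/HDF5), ROI lists (RLE JSON and CSV),
and response-call tables (CSV)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .movie import Movie
from .roi import ROI
from .traces import ResponseCall

_TIFF_SUFFIXES = {".tif", ".tiff"}
_HDF5_SUFFIXES = {".h5", ".hdf5"}


def save_movie(movie: Movie, path: str | Path) -> None:
    """Write as unsigned 16-bit: multi-page TIFF or an HDF5 dataset."""
    path = Path(path)
    arr = np.clip(np.round(movie.data), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(
            path,
            arr,
            imagej=True,
            metadata={"axes": "TYX", "finterval": movie.frame_interval},
        )
    elif path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("movie", data=arr)
            ds.attrs["frame_interval"] = movie.frame_interval
    else:
        raise ValueError(f"unsupported movie format: {path.suffix!r}")


def load_movie(path: str | Path, frame_interval: float | None = None) -> Movie:
    """Load a movie; frame interval comes from file metadata unless given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file not found: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.imagej_metadata or {}
        fi = frame_interval if frame_interval is not None else meta.get("finterval")
    elif path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as f:
            data = f["movie"][()]
            fi = frame_interval if frame_interval is not None else f["movie"].attrs.get("frame_interval")
    else:
        raise ValueError(f"unsupported movie format: {path.suffix!r}")
    if fi is None:
        raise ValueError(f"{path}: no frame interval in metadata; pass frame_interval")
    return Movie(data=np.asarray(data, dtype=np.float32), frame_interval=float(fi))


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a single-frame uint16 image (co-label channel)."""
    arr = np.clip(np.round(np.asarray(image)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), arr)


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    return tifffile.imread(path).astype(np.float32)


# -- ROI lists --------------------------------------------------------------


def _rle_encode(pixels: np.ndarray) -> list[list[int]]:
    """Row-wise run-length encoding of a sorted (n, 2) pixel array."""
    runs = []
    cur = None  # [row, col_start, length]
    for r, c in pixels.tolist():
        if cur is not None and r == cur[0] and c == cur[1] + cur[2]:
            cur[2] += 1
        else:
            if cur is not None:
                runs.append(cur)
            cur = [int(r), int(c), 1]
    if cur is not None:
        runs.append(cur)
    return runs


def _rle_decode(runs: list[list[int]]) -> np.ndarray:
    coords = []
    for r, c0, length in runs:
        for c in range(c0, c0 + length):
            coords.append((r, c))
    return np.asarray(coords, dtype=int)


def rois_to_json(rois: Sequence[ROI], path: str | Path) -> None:
    records = [
        {
            "roi_id": roi.roi_id,
            "source_stimulus": roi.source_stimulus,
            "sources": list(roi.sources),
            "rle": _rle_encode(roi.pixels),
        }
        for roi in rois
    ]
    Path(path).write_text(json.dumps(records, indent=1, sort_keys=True))


def rois_from_json(path: str | Path) -> list[ROI]:
    records = json.loads(Path(path).read_text())
    out = []
    for rec in records:
        roi = ROI(
            pixels=_rle_decode(rec["rle"]),
            source_stimulus=rec["source_stimulus"],
            sources=tuple(rec["sources"]),
        )
        roi.roi_id = rec["roi_id"]
        out.append(roi)
    return out


def rois_to_csv(rois: Sequence[ROI], path: str | Path) -> None:
    """ImageJ-style summary: label, centroid and area per ROI."""
    rows = []
    for roi in rois:
        cy, cx = roi.centroid
        rows.append(
            {
                "label": roi.roi_id or roi.source_stimulus,
                "centroid_y": cy,
                "centroid_x": cx,
                "area": roi.area,
            }
        )
    pd.DataFrame(rows, columns=["label", "centroid_y", "centroid_x", "area"]).to_csv(
        path, index=False, float_format="%.4f"
    )


# -- response calls ---------------------------------------------------------

_CALL_COLUMNS = [
    "roi_id",
    "stimulus",
    "concentration_M",
    "peak_value",
    "peak_frame",
    "baseline_at_peak",
    "dff",
    "responder",
]


def calls_to_csv(calls: Sequence[ResponseCall], path: str | Path) -> None:
    rows = [
        {
            "roi_id": c.roi_id,
            "stimulus": c.stimulus,
            "concentration_M": np.nan if c.concentration is None else c.concentration,
            "peak_value": c.peak_value,
            "peak_frame": c.peak_frame,
            "baseline_at_peak": c.baseline_at_peak,
            "dff": c.delta_f_over_f,
            "responder": c.responder,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, index=False, float_format="%.6g")


def calls_from_csv(path: str | Path) -> list[ResponseCall]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ResponseCall(
                roi_id=str(row.roi_id),
                stimulus=str(row.stimulus),
                concentration=None if pd.isna(row.concentration_M) else float(row.concentration_M),
                peak_value=float(row.peak_value),
                peak_frame=int(row.peak_frame),
                baseline_at_peak=float(row.baseline_at_peak),
                delta_f_over_f=float(row.dff),
                responder=bool(row.responder),
            )
        )
    return out
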