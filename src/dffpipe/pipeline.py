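"""End-to-end orchestration: register -> detect -> merge -> trace -> call ->
profile, plus the serializable run configuration."""

from __future__ import annotations

import contextlib
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .exceptions import PipelineError
from .movie import Movie
from .preprocess import FrameShifts, register_frames
from .profiling import ResponseMatrix, colabel_gate, overlap_summary, percent_responding
from .roi import ROI, DetectionParams, detect_local_rois, filter_candidates, merge_to_global
from .stimuli import StimulusSchedule
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    TuningClass,
    generate_colabel_image,
    generate_slice_movie,
    generate_stimulus_schedule,
)
from .traces import (
    DEFAULT_RESPONSE_WINDOW_S,
    RESPONSE_THRESHOLD,
    call_response,
    extract_trace,
    fit_baseline,
)

logger = logging.getLogger("dffpipe")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML unchanged."""

    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # stimuli for simulation: [label, molar concentration or None]
    stimuli: list = field(
        default_factory=lambda: [["SE", 1e-7], ["EU", None], ["NEU", None], ["KCl", None]]
    )
    detection: DetectionParams = field(default_factory=DetectionParams)
    response_window_s: float = DEFAULT_RESPONSE_WINDOW_S
    response_threshold: float = RESPONSE_THRESHOLD
    movie_path: str | None = None
    schedule_path: str | None = None
    colabel_path: str | None = None
    frame_interval: float | None = None  # override when file metadata is absent
    colabel_threshold: float | None = None
    # overlap summaries to compute: [[labels A...], [labels B...]]
    overlap_pairs: list = field(default_factory=lambda: [[["SE"], ["EU"]], [["SE"], ["NEU"]]])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulation", {})
        if isinstance(sim, dict):
            sim = _simulation_from_dict(sim)
        det = d.get("detection", {})
        if isinstance(det, dict):
            det = DetectionParams(**det)
        kwargs = {
            f.name: d[f.name]
            for f in dataclasses.fields(cls)
            if f.name in d and f.name not in ("simulation", "detection")
        }
        return cls(simulation=sim, detection=det, **kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Recursively convert tuples to lists and numpy scalars to Python ones."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _simulation_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("image_shape", "cell_radius_range", "baseline_intensity_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if d.get("tuning_classes") is not None:
        classes = []
        for c in d["tuning_classes"]:
            responses = {k: tuple(v) for k, v in c["responses"].items()}
            classes.append(TuningClass(label=c["label"], fraction=c["fraction"], responses=responses))
        d["tuning_classes"] = classes
    return SimulationConfig(**d)


@contextlib.contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done", name)


def analyze_movie(
    movie: Movie,
    schedule: StimulusSchedule,
    detection: DetectionParams | None = None,
    response_window_s: float = DEFAULT_RESPONSE_WINDOW_S,
    response_threshold: float = RESPONSE_THRESHOLD,
    colabel_image: np.ndarray | None = None,
    colabel_threshold: float | None = None,
) -> tuple[list[ROI], ResponseMatrix, FrameShifts]:
    """The full single-slice pipeline on in-memory data.

    register -> per-stimulus detection -> shape filtering -> global merge ->
    trace extraction -> baseline fit -> per-stimulus response calls.
    """
    detection = detection or DetectionParams()
    with _stage("register"):
        registered, shifts = register_frames(movie)
    with _stage("detect"):
        local_sets = []
        for ev in schedule:
            candidates = detect_local_rois(registered, ev, detection)
            local_sets.append((ev.label, filter_candidates(candidates, detection)))
    with _stage("merge"):
        global_rois = merge_to_global(local_sets, detection)
    with _stage("call"):
        calls = []
        for roi in global_rois:
            trace = extract_trace(registered, roi)
            baseline = fit_baseline(trace, schedule, response_window_s)
            for ev in schedule:
                calls.append(
                    call_response(trace, baseline, ev, response_window_s, response_threshold)
                )
    colabel = None
    if colabel_image is not None and colabel_threshold is not None:
        with _stage("colabel"):
            mask = colabel_gate(global_rois, colabel_image, colabel_threshold)
            colabel = {roi.roi_id: bool(m) for roi, m in zip(global_rois, mask)}
    matrix = ResponseMatrix(calls, colabel=colabel)
    return global_rois, matrix, shifts


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute a configured run and write all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(out / "run.log", config.seed)

    truth: GroundTruth | None = None
    colabel_image = None
    if config.simulate:
        with _stage("simulate"):
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            stimuli = [(lab, conc) for lab, conc in config.stimuli]
            schedule = generate_stimulus_schedule(sim, stimuli)
            movie, truth = generate_slice_movie(sim, schedule)
            if config.colabel_threshold is not None:
                colabel_image = generate_colabel_image(sim, truth)
            schedule.to_json(out / "schedule.json")
            truth.to_json(out / "ground_truth.json")
    else:
        with _stage("load"):
            if not config.movie_path or not Path(config.movie_path).exists():
                raise FileNotFoundError(f"movie path does not exist: {config.movie_path!r}")
            if not config.schedule_path or not Path(config.schedule_path).exists():
                raise FileNotFoundError(f"schedule path does not exist: {config.schedule_path!r}")
            movie = dio.load_movie(config.movie_path, config.frame_interval)
            schedule = StimulusSchedule.from_json(config.schedule_path)
            if config.colabel_path:
                colabel_image = dio.load_image(config.colabel_path)

    global_rois, matrix, shifts = analyze_movie(
        movie,
        schedule,
        detection=config.detection,
        response_window_s=config.response_window_s,
        response_threshold=config.response_threshold,
        colabel_image=colabel_image,
        colabel_threshold=config.colabel_threshold,
    )

    with _stage("write"):
        shifts.to_csv(out / "shifts.csv")
        dio.rois_to_json(global_rois, out / "rois.json")
        dio.rois_to_csv(global_rois, out / "rois.csv")
        all_calls = [c for rid in matrix.roi_ids for c in matrix.calls_for_roi(rid)]
        dio.calls_to_csv(all_calls, out / "calls.csv")
        summary = _summarize(config, matrix, truth)
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        config.save(out / "config_resolved.yaml")
    logger.info("run complete: %d global ROIs", len(global_rois))
    return out


def _summarize(config: PipelineConfig, matrix: ResponseMatrix, truth: GroundTruth | None) -> dict:
    summary: dict = {"n_global_rois": len(matrix.roi_ids), "seed": config.seed}
    pct = {}
    for label in matrix.labels:
        try:
            pct[label] = percent_responding(matrix, label, "all_rois")
        except ValueError:
            pct[label] = None
    summary["percent_responding"] = pct
    overlaps = []
    for a_labels, b_labels in config.overlap_pairs:
        have = set(matrix.labels)
        if not (set(a_labels) <= have and set(b_labels) <= have):
            continue
        venn = overlap_summary(matrix, a_labels, b_labels)
        overlaps.append(
            {
                "a": list(a_labels),
                "b": list(b_labels),
                "n_a": venn.n_a,
                "n_b": venn.n_b,
                "n_ab": venn.n_ab,
                "pct_b_given_a": venn.pct_b_given_a,
            }
        )
    summary["overlaps"] = overlaps
    if truth is not None:
        summary["n_true_cells"] = truth.n_cells
    return summary


def _setup_run_logging(log_path: Path, seed: int) -> None:
    for h in list(logger.handlers):  # avoid handler leak across runs
        if isinstance(h, logging.FileHandler):
            logger.removeHandler(h)
            h.close()
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    import scipy
    import skimage

    from . import __version__

    logger.info(
        "dffpipe %s | numpy %s scipy %s scikit-image %s | seed %d",
        __version__,
        np.__version__,
        scipy.__version__,
        skimage.__version__,
        seed,
    )
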