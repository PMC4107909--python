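"""Self-contained recovery benchmarks: simulate known ground truth, run the
full pipeline (register -> detect -> merge -> dF/F -> threshold -> profile)
and measure how well the population statistics are recovered.

Used by the acceptance test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import analyze_movie
from .profiling import ResponseMatrix, overlap_summary, percent_responding
from .roi import DetectionParams
from .synthetic import (
    SimulationConfig,
    TuningClass,
    generate_slice_movie,
    generate_stimulus_schedule,
    match_rois_to_truth,
)


def _acceptance_sim(seed: int, **overrides) -> SimulationConfig:
    """Desk-scale recording: short epochs, default noise and kinetics."""
    defaults = dict(
        image_shape=(160, 160),
        frame_interval=1.0,
        n_cells=60,
        stimulus_duration_s=30.0,
        inter_stimulus_gap_s=45.0,
        initial_delay_s=40.0,
        post_stimulus_s=25.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class OverlapBenchmarkResult:
    pct_eu_given_se: float
    pct_neu_given_se: float
    n_se: int  # pooled count of pipeline-identified SE responders
    n_rois: int


def overlap_benchmark(seeds=(1, 2, 3)) -> OverlapBenchmarkResult:
    """3 simulated slices, ~30 SE-tuned cells each, co-tuning
    P(EU|SE)=0.65 and P(NEU|SE)=0.05; full pipeline, pooled overlap."""
    classes = [
        TuningClass("se_tuned", 0.5, {"SE": (1.0, 0.8), "EU": (0.65, 0.8), "NEU": (0.05, 0.8)})
    ]
    matrices = []
    for seed in seeds:
        cfg = _acceptance_sim(seed, tuning_classes=classes)
        schedule = generate_stimulus_schedule(cfg, [("SE", 1e-7), ("EU", None), ("NEU", None)])
        movie, _ = generate_slice_movie(cfg, schedule)
        _, matrix, _ = analyze_movie(movie, schedule, response_window_s=30.0)
        matrices.append(matrix)
    pooled = ResponseMatrix.concat(matrices)
    eu = overlap_summary(pooled, "SE", "EU")
    neu = overlap_summary(pooled, "SE", "NEU")
    return OverlapBenchmarkResult(
        pct_eu_given_se=eu.pct_b_given_a if eu.pct_b_given_a is not None else float("nan"),
        pct_neu_given_se=neu.pct_b_given_a if neu.pct_b_given_a is not None else float("nan"),
        n_se=eu.n_a,
        n_rois=len(pooled.roi_ids),
    )


@dataclass
class ControlRateResult:
    pct_responding: float
    n_rois: int
    n_true_cells: int


def control_rate_benchmark(seed: int = 7, n_cells_total: int = 1000) -> ControlRateResult:
    """Control-slice activation rate: cells are SE-tuned with the generator
    default fraction; a depolarizing reference epoch reveals every cell so
    the 'all ROIs' denominator matches the full population."""
    per_slice = [n_cells_total // 3 + (1 if k < n_cells_total % 3 else 0) for k in range(3)]
    matrices = []
    n_true = 0
    for k, n_cells in enumerate(per_slice):
        cfg = _acceptance_sim(
            seed + k,
            image_shape=(512, 512),
            frame_interval=2.0,
            n_cells=n_cells,
            cell_radius_range=(4.0, 6.0),
        )
        schedule = generate_stimulus_schedule(cfg, [("SE", 1e-7), ("KCl", None)])
        movie, truth = generate_slice_movie(cfg, schedule)
        _, matrix, _ = analyze_movie(movie, schedule, response_window_s=30.0)
        matrices.append(matrix)
        n_true += truth.n_cells
    pooled = ResponseMatrix.concat(matrices)
    pct = percent_responding(pooled, "SE", "all_rois")
    return ControlRateResult(pct_responding=pct, n_rois=len(pooled.roi_ids), n_true_cells=n_true)


@dataclass
class DetectionResult:
    recall: float
    precision: float
    n_true_cells: int


def detection_benchmark(seed: int = 17, amplitude: float = 0.4) -> DetectionResult:
    """Global-ROI recall/precision against ground truth at a given true
    amplitude under default noise."""
    classes = [TuningClass("resp", 1.0, {"SE": (1.0, amplitude)})]
    cfg = _acceptance_sim(
        seed, image_shape=(288, 288), n_cells=100, tuning_classes=classes
    )
    schedule = generate_stimulus_schedule(cfg, [("SE", None)])
    movie, truth = generate_slice_movie(cfg, schedule)
    rois, _, _ = analyze_movie(movie, schedule, response_window_s=30.0)
    recall, precision, _ = match_rois_to_truth(rois, truth)
    return DetectionResult(recall=recall, precision=precision, n_true_cells=truth.n_cells)


@dataclass
class FidelityResult:
    mean_dff: float
    n_cells: int


def dff_fidelity_benchmark(seed: int = 42, amplitude: float = 0.5,
                           n_cells_total: int = 200) -> FidelityResult:
    """Mean pipeline-estimated dF/F over cells with a known true amplitude.

    0.5 s frames keep the 3-frame peak smoothing well inside the transient.
    """
    classes = [TuningClass("resp", 1.0, {"SE": (1.0, amplitude)})]
    dffs: list[float] = []
    per_slice = n_cells_total // 2
    for k in range(2):
        cfg = _acceptance_sim(
            seed + k,
            image_shape=(288, 288),
            frame_interval=0.5,
            n_cells=per_slice,
            stimulus_duration_s=30.0,
            post_stimulus_s=20.0,
            tuning_classes=classes,
        )
        schedule = generate_stimulus_schedule(cfg, [("SE", None)])
        movie, truth = generate_slice_movie(cfg, schedule)
        rois, matrix, _ = analyze_movie(movie, schedule, response_window_s=30.0)
        _, _, matched = match_rois_to_truth(rois, truth)
        for rid in matrix.roi_ids:
            d = matrix.dff(rid, "SE")
            if d is not None:
                dffs.append(d)
    return FidelityResult(mean_dff=float(np.mean(dffs)), n_cells=len(dffs))


def default_detection_params() -> DetectionParams:
    return DetectionParams()
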