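"""Forward model: synthetic slice movies, co-label images and behavior tables.

Everything downstream (registration, ROI detection, dF/F calling, population
summaries) is tested by recovering the latents recorded in :class:`GroundTruth`.

The generative model for each pixel is::

    F(t) = sum_cells disk(center, radius) * B0 * exp(-t / bleach_tau)
           * (1 + sum_events a[cell, event] * kernel(t - t_onset))
           + N(0, noise_sigma)

where ``kernel`` is a difference of exponentials normalized to unit peak.
Rigid drift accumulates at ``drift_per_frame`` pixels per frame (applied as a
rounded integer translation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .exceptions import ConfigError, SimulationError
from .movie import Movie
from .stimuli import StimulusEvent, StimulusSchedule

# Default co-tuning structure for control-slice simulations: a small fraction
# of cells is tuned to the sulfated-estrogen stimulus, and those cells respond
# to estrus urine far more often than to non-estrus urine.
DEFAULT_SE_TUNED_FRACTION = 0.10
DEFAULT_P_EU_GIVEN_SE = 0.65
DEFAULT_P_NEU_GIVEN_SE = 0.05


@dataclass
class TuningClass:
    """A population class: its fraction and per-stimulus response profile.

    ``responses`` maps stimulus label to ``(probability, amplitude)``: each
    cell of the class responds to that stimulus with the given probability,
    with peak dF/F of ``amplitude`` (scaled by the Hill factor when the
    stimulus carries a concentration).
    """

    label: str
    fraction: float
    responses: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Knobs of the slice-movie forward model. All times in seconds."""

    image_shape: tuple[int, int] = (128, 128)
    n_frames: int | None = None  # None: sized automatically to cover the schedule
    frame_interval: float = 0.5
    n_cells: int = 40
    cell_radius_range: tuple[float, float] = (4.0, 6.0)
    baseline_intensity_range: tuple[float, float] = (1500.0, 3000.0)
    bleach_tau: float = 600.0
    noise_sigma: float = 15.0
    transient_amplitude: float = 0.8
    transient_rise_tau: float = 1.0
    transient_decay_tau: float = 8.0
    drift_per_frame: float = 0.02
    tuning_classes: list[TuningClass] | None = None
    se_tuned_fraction: float = DEFAULT_SE_TUNED_FRACTION
    p_eu_given_se: float = DEFAULT_P_EU_GIVEN_SE
    p_neu_given_se: float = DEFAULT_P_NEU_GIVEN_SE
    hill_ec50: float = 1e-9
    hill_coefficient: float = 1.0
    # schedule layout
    stimulus_duration_s: float = 60.0
    inter_stimulus_gap_s: float = 120.0
    initial_delay_s: float = 60.0
    post_stimulus_s: float = 30.0
    # a depolarizing reference stimulus (e.g. high K+) activates every cell,
    # giving activity-based detection an "all cells" denominator
    reference_stimulus_label: str = "KCl"
    reference_amplitude: float = 1.0
    colabel_fraction: float = 0.4
    colabel_intensity: float = 1000.0
    min_cell_separation: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        if h < 8 or w < 8:
            raise ConfigError("image_shape too small")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be non-negative")
        lo, hi = self.cell_radius_range
        if lo <= 0 or hi < lo:
            raise ConfigError("cell_radius_range must be positive and ordered")
        if self.bleach_tau <= 0 or self.transient_rise_tau <= 0 or self.transient_decay_tau <= 0:
            raise ConfigError("time constants must be positive")
        if self.transient_rise_tau >= self.transient_decay_tau:
            raise ConfigError("transient_rise_tau must be smaller than transient_decay_tau")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be non-negative")
        total = sum(c.fraction for c in self.resolved_tuning_classes())
        if total > 1.0 + 1e-9:
            raise ConfigError("tuning class fractions must sum to <= 1")

    def resolved_tuning_classes(self) -> list[TuningClass]:
        """Explicit classes, or the default control-slice structure."""
        if self.tuning_classes is not None:
            return self.tuning_classes
        a = self.transient_amplitude
        return [
            TuningClass(
                label="se_tuned",
                fraction=self.se_tuned_fraction,
                responses={
                    "SE": (1.0, a),
                    "EU": (self.p_eu_given_se, a),
                    "NEU": (self.p_neu_given_se, a),
                },
            )
        ]


@dataclass
class GroundTruth:
    """Every latent of one simulated slice, the oracle for recovery tests."""

    cell_centers: np.ndarray  # (n_cells, 2) float, (row, col)
    cell_radii: np.ndarray  # (n_cells,) float
    cell_baselines: np.ndarray  # (n_cells,) float, resting fluorescence B0
    class_of_cell: list[str]
    event_labels: list[str]  # one per scheduled event, aligned with columns
    event_concentrations: list[float | None]
    true_responder: np.ndarray  # (n_cells, n_events) bool
    true_amplitude: np.ndarray  # (n_cells, n_events) float, dF/F units
    colabel_positive: np.ndarray  # (n_cells,) bool

    @property
    def n_cells(self) -> int:
        return len(self.cell_radii)

    def responders_to_label(self, label: str) -> np.ndarray:
        """Boolean mask of cells responding to any event with this label."""
        cols = [i for i, lab in enumerate(self.event_labels) if lab == label]
        if not cols:
            raise KeyError(f"no event with label {label!r}")
        return self.true_responder[:, cols].any(axis=1)

    def to_json(self, path: str | Path) -> None:
        d = {
            "cell_centers": self.cell_centers.tolist(),
            "cell_radii": self.cell_radii.tolist(),
            "cell_baselines": self.cell_baselines.tolist(),
            "class_of_cell": self.class_of_cell,
            "event_labels": self.event_labels,
            "event_concentrations": self.event_concentrations,
            "true_responder": self.true_responder.astype(int).tolist(),
            "true_amplitude": self.true_amplitude.tolist(),
            "colabel_positive": self.colabel_positive.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cell_centers=np.asarray(d["cell_centers"], dtype=float),
            cell_radii=np.asarray(d["cell_radii"], dtype=float),
            cell_baselines=np.asarray(d["cell_baselines"], dtype=float),
            class_of_cell=list(d["class_of_cell"]),
            event_labels=list(d["event_labels"]),
            event_concentrations=[None if c is None else float(c) for c in d["event_concentrations"]],
            true_responder=np.asarray(d["true_responder"], dtype=bool),
            true_amplitude=np.asarray(d["true_amplitude"], dtype=float),
            colabel_positive=np.asarray(d["colabel_positive"], dtype=bool),
        )


def transient_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials response kernel, normalized to unit peak."""
    t = np.asarray(t, dtype=float)
    tc = np.clip(t, 0.0, None)
    k = np.where(t >= 0, np.exp(-tc / decay_tau) - np.exp(-tc / rise_tau), 0.0)
    t_peak = math.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)
    norm = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    return k / norm


def hill_factor(concentration: float | None, ec50: float, coefficient: float) -> float:
    """Fractional occupancy at a molar concentration; 1.0 when unspecified."""
    if concentration is None:
        return 1.0
    c = float(concentration)
    if c <= 0:
        return 0.0
    return c**coefficient / (c**coefficient + ec50**coefficient)


def generate_stimulus_schedule(
    config: SimulationConfig, stimuli: list[tuple[str, float | None]]
) -> StimulusSchedule:
    """Lay out delivery epochs: an initial delay, then fixed-length epochs
    separated by fixed gaps, in the order given."""
    config.validate()
    if not stimuli:
        raise ConfigError("stimulus list must be non-empty")
    if config.inter_stimulus_gap_s < 5.0 * config.transient_decay_tau:
        raise ConfigError(
            "inter_stimulus_gap_s must be at least 5x transient_decay_tau "
            f"({5.0 * config.transient_decay_tau:g} s)"
        )
    fi = config.frame_interval
    dur_f = int(round(config.stimulus_duration_s / fi))
    gap_f = int(round(config.inter_stimulus_gap_s / fi))
    delay_f = int(round(config.initial_delay_s / fi))
    events = []
    for k, (label, conc) in enumerate(stimuli):
        onset = delay_f + k * (dur_f + gap_f)
        events.append(
            StimulusEvent(
                label=str(label),
                concentration=None if conc is None else float(conc),
                onset_frame=onset,
                offset_frame=onset + dur_f,
            )
        )
    required = events[-1].offset_frame + int(round(config.post_stimulus_s / fi))
    n_frames = config.n_frames if config.n_frames is not None else required
    if required > n_frames:
        raise ConfigError(
            f"schedule needs {required} frames but the movie has only {n_frames}"
        )
    return StimulusSchedule(events=events, frame_interval=fi, n_frames=n_frames)


def _place_cells(config: SimulationConfig, rng: np.random.Generator):
    """Rejection-sample disk centers/radii inside the frame, non-overlapping."""
    h, w = config.image_shape
    lo, hi = config.cell_radius_range
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(config.n_cells):
        for _attempt in range(1000):
            r = rng.uniform(lo, hi)
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            if cy - r < 0 or cy + r > h - 1 or cx - r < 0 or cx + r > w - 1:
                continue
            ok = True
            for (py, px), pr in zip(centers, radii):
                if math.hypot(cy - py, cx - px) < r + pr + config.min_cell_separation:
                    ok = False
                    break
            if ok:
                centers.append((cy, cx))
                radii.append(r)
                break
        else:
            raise SimulationError(
                f"could not place cell {len(centers)} after 1000 draws; "
                "reduce n_cells or cell size"
            )
    return np.asarray(centers, dtype=float), np.asarray(radii, dtype=float)


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    classes = config.resolved_tuning_classes()
    u = rng.random(config.n_cells)
    out = []
    for ui in u:
        acc = 0.0
        label = "silent"
        for cl in classes:
            acc += cl.fraction
            if ui < acc:
                label = cl.label
                break
        out.append(label)
    return out


def _draw_responses(
    config: SimulationConfig,
    schedule: StimulusSchedule,
    class_of_cell: list[str],
    rng: np.random.Generator,
):
    """Per (cell, event) responder flags and dF/F amplitudes.

    Responder identity is drawn once per (cell, stimulus label) so repeated
    deliveries and dose series stay consistent; concentration only scales the
    amplitude through the Hill factor.
    """
    classes = {c.label: c for c in config.resolved_tuning_classes()}
    labels = [lab for lab in schedule.labels if lab != config.reference_stimulus_label]
    n = config.n_cells
    resp_by_label: dict[str, np.ndarray] = {}
    amp_by_label: dict[str, np.ndarray] = {}
    for lab in labels:
        p = np.zeros(n)
        a = np.zeros(n)
        for i, cl_label in enumerate(class_of_cell):
            cl = classes.get(cl_label)
            if cl is not None and lab in cl.responses:
                p[i], a[i] = cl.responses[lab]
        resp_by_label[lab] = rng.random(n) < p
        amp_by_label[lab] = a

    n_events = len(schedule.events)
    responder = np.zeros((n, n_events), dtype=bool)
    amplitude = np.zeros((n, n_events), dtype=float)
    for j, ev in enumerate(schedule.events):
        if ev.label == config.reference_stimulus_label:
            responder[:, j] = True
            amplitude[:, j] = config.reference_amplitude
        else:
            hf = hill_factor(ev.concentration, config.hill_ec50, config.hill_coefficient)
            responder[:, j] = resp_by_label[ev.label]
            amplitude[:, j] = amp_by_label[ev.label] * hf * resp_by_label[ev.label]
    return responder, amplitude


def cell_pixels(
    center: tuple[float, float], radius: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col index arrays of the rendered disk."""
    return draw_disk(center, radius, shape=shape)


def _integer_translate(img: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    """Translate image content by (dy, dx); uncovered pixels get ``fill``."""
    out = np.full_like(img, fill)
    h, w = img.shape
    ys0, ys1 = max(0, -dy), min(h, h - dy)
    xs0, xs1 = max(0, -dx), min(w, w - dx)
    if ys1 <= ys0 or xs1 <= xs0:
        return out
    out[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx] = img[ys0:ys1, xs0:xs1]
    return out


def render_movie(
    config: SimulationConfig,
    truth: GroundTruth,
    schedule: StimulusSchedule,
    drift: bool = False,
) -> np.ndarray:
    """Deterministic (noise-free) forward render from the recorded latents.

    With ``drift=False`` this is the exact clean movie;
    :func:`generate_slice_movie` adds drift and noise on top.
    """
    baselines = truth.cell_baselines
    h, w = config.image_shape
    n_frames = schedule.n_frames
    times = np.arange(n_frames) * schedule.frame_interval
    bleach = np.exp(-times / config.bleach_tau)

    pix = [
        cell_pixels(tuple(c), r, (h, w))
        for c, r in zip(truth.cell_centers, truth.cell_radii)
    ]
    base = np.zeros((h, w), dtype=np.float64)
    for (rr, cc), b0 in zip(pix, baselines):
        base[rr, cc] += b0

    # activity[t, cell]: summed kernel contributions across events
    activity = np.zeros((n_frames, truth.n_cells), dtype=np.float64)
    for j, ev in enumerate(schedule.events):
        amps = truth.true_amplitude[:, j]
        if not np.any(amps > 0):
            continue
        k = transient_kernel(times - schedule.onset_seconds(ev), config.transient_rise_tau,
                             config.transient_decay_tau)
        activity += np.outer(k, amps)

    out = np.empty((n_frames, h, w), dtype=np.float32)
    for t in range(n_frames):
        frame = base * bleach[t]
        active = np.nonzero(activity[t] > 1e-12)[0]
        for c in active:
            rr, cc = pix[c]
            frame[rr, cc] += baselines[c] * activity[t, c] * bleach[t]
        if drift:
            d = int(round(config.drift_per_frame * t))
            if d != 0:
                frame = _integer_translate(frame, d, d, 0.0)
        out[t] = frame
    return out


def generate_slice_movie(
    config: SimulationConfig,
    schedule: StimulusSchedule,
    rng: np.random.Generator | None = None,
) -> tuple[Movie, GroundTruth]:
    """Simulate one slice recording and return the movie plus its latents."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    centers, radii = _place_cells(config, rng)
    class_of_cell = _assign_classes(config, rng)
    responder, amplitude = _draw_responses(config, schedule, class_of_cell, rng)
    colabel = rng.random(config.n_cells) < config.colabel_fraction
    b_lo, b_hi = config.baseline_intensity_range
    baselines = rng.uniform(b_lo, b_hi, size=config.n_cells)

    truth = GroundTruth(
        cell_centers=centers,
        cell_radii=radii,
        cell_baselines=baselines,
        class_of_cell=class_of_cell,
        event_labels=[ev.label for ev in schedule.events],
        event_concentrations=[ev.concentration for ev in schedule.events],
        true_responder=responder,
        true_amplitude=amplitude,
        colabel_positive=colabel,
    )

    data = render_movie(config, truth, schedule,
                        drift=config.drift_per_frame != 0)
    if config.noise_sigma > 0:
        data += np.float32(config.noise_sigma) * rng.standard_normal(
            size=data.shape, dtype=np.float32
        )
    movie = Movie(data=data, frame_interval=config.frame_interval)
    return movie, truth


def generate_colabel_image(
    config: SimulationConfig, truth: GroundTruth, seed: int | None = None
) -> np.ndarray:
    """Second-channel still image: bright disks where cells are co-labeled."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    h, w = config.image_shape
    img = np.zeros((h, w), dtype=np.float64)
    for center, radius, pos in zip(truth.cell_centers, truth.cell_radii, truth.colabel_positive):
        if pos:
            rr, cc = cell_pixels(tuple(center), radius, (h, w))
            img[rr, cc] += config.colabel_intensity
    if config.noise_sigma > 0:
        img += rng.normal(0.0, config.noise_sigma, size=img.shape)
    return img.astype(np.float32)


def match_rois_to_truth(rois, truth: GroundTruth) -> tuple[float, float, np.ndarray]:
    """Greedy centroid matching of detected ROIs against true cells.

    A detected ROI matches a true cell when their centroid distance is at most
    that cell's radius; each cell and each ROI is used at most once. Returns
    ``(recall, precision, matched_cell_mask)``.
    """
    matched_cells = np.zeros(truth.n_cells, dtype=bool)
    pairs = []
    for i, roi in enumerate(rois):
        cy, cx = roi.centroid
        d = np.hypot(truth.cell_centers[:, 0] - cy, truth.cell_centers[:, 1] - cx)
        j = int(np.argmin(d))
        if d[j] <= truth.cell_radii[j]:
            pairs.append((i, j, d[j]))
    used_rois: set[int] = set()
    for i, j, _ in sorted(pairs, key=lambda p: p[2]):
        if i in used_rois or matched_cells[j]:
            continue
        used_rois.add(i)
        matched_cells[j] = True
    n_match = int(matched_cells.sum())
    recall = n_match / truth.n_cells if truth.n_cells else 1.0
    precision = n_match / len(rois) if rois else 1.0
    return recall, precision, matched_cells


# ---------------------------------------------------------------------------
# behavior


@dataclass
class BehaviorGroup:
    label: str
    n_animals: int
    mount_rate: float  # expected mounts per session
    mean_mount_duration: float  # seconds
    session_length: float  # seconds


@dataclass
class BehaviorConfig:
    groups: list[BehaviorGroup]
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ConfigError("at least one behavior group required")
        for g in self.groups:
            if g.mount_rate < 0:
                raise ConfigError(f"group {g.label!r}: mount_rate must be >= 0")
            if g.session_length <= 0:
                raise ConfigError(f"group {g.label!r}: session_length must be > 0")
            if g.mean_mount_duration <= 0:
                raise ConfigError(f"group {g.label!r}: mean_mount_duration must be > 0")


def generate_behavior_table(config: BehaviorConfig, rng: np.random.Generator | None = None):
    """Draw per-animal mount events: Poisson counts, uniform starts,
    exponential durations truncated to the session, non-overlap by rejection."""
    from .behavior import BehaviorEventTable  # local import to avoid a cycle

    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    session = config.groups[0].session_length
    animals = []
    rows = []
    for g in config.groups:
        if g.session_length != session:
            raise ConfigError("all groups must share one session_length")
        for i in range(g.n_animals):
            animal_id = f"{g.label}_{i:03d}"
            animals.append({"animal_id": animal_id, "group": g.label})
            n_events = rng.poisson(g.mount_rate)
            placed: list[tuple[float, float]] = []
            for _ in range(n_events):
                for _attempt in range(1000):
                    start = rng.uniform(0.0, g.session_length)
                    dur = rng.exponential(g.mean_mount_duration)
                    end = min(start + dur, g.session_length)
                    if end <= start:
                        continue
                    if all(end <= s or start >= e for s, e in placed):
                        placed.append((start, end))
                        break
                else:
                    raise SimulationError(
                        f"could not place a non-overlapping mount event for {animal_id}"
                    )
            for start, end in sorted(placed):
                rows.append(
                    {
                        "animal_id": animal_id,
                        "group": g.label,
                        "event_start_s": start,
                        "event_end_s": end,
                    }
                )
    events = pd.DataFrame(rows, columns=["animal_id", "group", "event_start_s", "event_end_s"])
    roster = pd.DataFrame(animals, columns=["animal_id", "group"])
    return BehaviorEventTable(animals=roster, events=events, session_length=session)
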