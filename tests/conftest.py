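import numpy as np
import pytest

import dffpipe as dp


def fast_config(**overrides) -> dp.SimulationConfig:
    """Small, quick-to-render simulation; epochs shortened accordingly."""
    defaults = dict(
        image_shape=(96, 96),
        frame_interval=1.0,
        n_cells=10,
        cell_radius_range=(3.5, 5.0),
        stimulus_duration_s=20.0,
        inter_stimulus_gap_s=45.0,
        initial_delay_s=30.0,
        post_stimulus_s=15.0,
        drift_per_frame=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return dp.SimulationConfig(**defaults)


def all_respond_class(amplitude: float, labels=("SE",)) -> list:
    """One tuning class covering every cell, responding to all given labels."""
    return [dp.TuningClass("resp", 1.0, {lab: (1.0, amplitude) for lab in labels})]


@pytest.fixture(scope="session")
def default_slice():
    """A moderately sized slice with default noise, shared across tests."""
    cfg = fast_config(
        n_cells=16,
        image_shape=(128, 128),
        tuning_classes=all_respond_class(0.8, labels=("SE",)),
        seed=11,
    )
    schedule = dp.generate_stimulus_schedule(cfg, [("SE", None)])
    movie, truth = dp.generate_slice_movie(cfg, schedule)
    return cfg, schedule, movie, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
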