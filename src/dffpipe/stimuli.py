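"""Stimulus schedules: ordered delivery epochs aligned to movie frames."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .exceptions import ConfigError


@dataclass(frozen=True)
class StimulusEvent:
    """One delivery epoch.

    ``onset_frame`` is the first frame of the epoch and ``offset_frame`` the
    first frame after it (half-open interval).  ``concentration`` is molar and
    may be ``None`` for undiluted/complex stimuli (e.g. urine).
    """

    label: str
    concentration: float | None
    onset_frame: int
    offset_frame: int

    def __post_init__(self) -> None:
        if self.offset_frame <= self.onset_frame:
            raise ConfigError(
                f"event {self.label!r}: offset_frame ({self.offset_frame}) must be "
                f"greater than onset_frame ({self.onset_frame})"
            )
        if self.onset_frame < 0:
            raise ConfigError(f"event {self.label!r}: negative onset frame")

    @property
    def duration_frames(self) -> int:
        return self.offset_frame - self.onset_frame


@dataclass
class StimulusSchedule:
    """Non-overlapping stimulus events delivered to one movie."""

    events: list[StimulusEvent]
    frame_interval: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.n_frames <= 0:
            raise ConfigError("n_frames must be positive")
        prev_end = -1
        for ev in self.events:
            if ev.onset_frame <= prev_end:
                raise ConfigError("stimulus events must be in order and non-overlapping")
            if ev.offset_frame > self.n_frames:
                raise ConfigError(
                    f"event {ev.label!r} ends at frame {ev.offset_frame}, "
                    f"beyond the movie ({self.n_frames} frames)"
                )
            prev_end = ev.offset_frame - 1

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def labels(self) -> list[str]:
        """Distinct stimulus labels in delivery order."""
        seen: list[str] = []
        for ev in self.events:
            if ev.label not in seen:
                seen.append(ev.label)
        return seen

    def onset_seconds(self, event: StimulusEvent) -> float:
        return event.onset_frame * self.frame_interval

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "frame_interval": self.frame_interval,
            "n_frames": self.n_frames,
            "events": [
                {
                    "label": ev.label,
                    "concentration": ev.concentration,
                    "onset_frame": ev.onset_frame,
                    "offset_frame": ev.offset_frame,
                }
                for ev in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        events = [
            StimulusEvent(
                label=e["label"],
                concentration=e["concentration"],
                onset_frame=int(e["onset_frame"]),
                offset_frame=int(e["offset_frame"]),
            )
            for e in d["events"]
        ]
        return cls(events=events, frame_interval=float(d["frame_interval"]), n_frames=int(d["n_frames"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusSchedule":
        return cls.from_dict(json.loads(Path(path).read_text()))
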