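"""Core audio containers shared across the package.

An :class:`AudioScene` is a mono waveform with its sample rate and an
optional list of ground-truth event annotations (onset, category, level,
duration).  Scenes are the common currency between the synthetic generator,
the acoustic front-end and the network-activation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sound-event categories used for annotation and analysis.  The first five
#: can be synthesized; ``animal`` and ``other`` exist only as labels for
#: externally annotated events.
EVENT_CATEGORIES = ("speech", "music", "vocal", "vehicle", "tapping", "animal", "other")


@dataclass(frozen=True)
class SceneEvent:
    """Ground-truth annotation of one sound event in a scene."""

    onset_s: float
    category: str
    level_db: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.category not in EVENT_CATEGORIES:
            raise ValueError(f"unknown event category {self.category!r}")
        if self.duration_s <= 0:
            raise ValueError("event duration must be positive")


@dataclass
class AudioScene:
    """Mono waveform with sample rate and optional event annotations."""

    samples: np.ndarray
    sample_rate: int
    annotations: list[SceneEvent] | None = None
    scene_id: str = field(default="scene")

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("scene must be mono (1-D samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("scene contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate
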