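"""Behavioral salience curves and salient-event detection.

Salience is measured behaviorally as the percentage of subjects attending
to a scene at each moment.  Salient events are peaks in the (smoothed)
derivative of that curve — moments when many subjects begin attending
together.  Each event's strength combines the height of the slope at the
peak with the maximum percentage of subjects attending within the 4 s that
follow; only the strongest fraction (default 50%) is kept for event-based
analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .scene import EVENT_CATEGORIES, SceneEvent
from .smoothing import smoothed_derivative


@dataclass
class SalienceCurve:
    """Percent-attending time series at 10 Hz."""

    values: np.ndarray
    rate: float = 10.0
    scene_id: str = "scene"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0.0 or self.values.max() > 100.0:
            raise ValueError("salience values must lie in [0, 100]")


@dataclass(frozen=True)
class SalientEvent:
    time_s: float
    strength: float
    category: str = "other"

    def __post_init__(self) -> None:
        if self.category not in EVENT_CATEGORIES:
            raise ValueError(f"unknown event category {self.category!r}")
        if not math.isfinite(self.strength):
            raise ValueError("event strength must be finite")


def salience_from_attention(attention: np.ndarray, rate: float = 10.0,
                            scene_id: str = "scene") -> SalienceCurve:
    """Percent attending from a subjects x time binary attention matrix."""
    a = np.asarray(attention)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("attention matrix must be subjects x time with >= 2 subjects")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("attention matrix must be binary")
    return SalienceCurve(values=a.mean(axis=0) * 100.0, rate=rate, scene_id=scene_id)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def detect_salient_events(curve: SalienceCurve, keep_fraction: float = 0.5,
                          noise_floor_sd: float = 0.5,
                          strength_window_s: float = 4.0,
                          min_separation_s: float = 1.0,
                          annotations: list[SceneEvent] | None = None
                          ) -> list[SalientEvent]:
    """Detect salient events as peaks in the smoothed salience derivative.

    Candidate peaks below ``noise_floor_sd`` standard deviations of the
    derivative are ignored, and peaks closer than ``min_separation_s`` are
    merged into the larger one (smoothing ripple would otherwise split one
    rise into several candidates).  Strength is the sum of the z-scored
    slope height and the z-scored maximum of the curve in the following
    ``strength_window_s``; the top ``keep_fraction`` of candidates by
    strength is returned, sorted by time.  Categories come from the nearest
    ground-truth annotation when one is supplied.
    """
    if curve.values.size / curve.rate < 10.0:
        raise ValueError("salience curve must be at least 10 s long")
    d = smoothed_derivative(curve.values, curve.rate)
    floor = noise_floor_sd * d.std()
    if d.std() == 0.0:
        return []
    peaks, props = sps.find_peaks(d, height=floor,
                                  distance=max(1, int(round(min_separation_s
                                                            * curve.rate))))
    if peaks.size == 0:
        return []
    heights = props["peak_heights"]
    win = int(round(strength_window_s * curve.rate))
    ceilings = np.array([curve.values[p: p + win + 1].max() for p in peaks])
    strength = _zscore(heights) + _zscore(ceilings)
    n_keep = math.ceil(keep_fraction * peaks.size)
    order = np.argsort(strength)[::-1][:n_keep]
    kept = sorted(order, key=lambda i: peaks[i])
    events = []
    for i in kept:
        t = peaks[i] / curve.rate
        category = "other"
        if annotations:
            nearest = min(annotations, key=lambda ev: abs(ev.onset_s - t))
            category = nearest.category
        events.append(SalientEvent(time_s=float(t), strength=float(strength[i]),
                                   category=category))
    return events
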