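"""File I/O: PCM WAV scenes, annotation sidecars, and tab-separated tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .behavior import SalientEvent
from .scene import AudioScene, SceneEvent


def write_wav(path: str | Path, scene: AudioScene) -> None:
    """Write a scene as 16-bit PCM WAV (values clipped to [-1, 1])."""
    x = np.clip(scene.samples, -1.0, 1.0)
    wavfile.write(str(path), scene.sample_rate, (x * 32767.0).astype(np.int16))


def read_wav(path: str | Path) -> AudioScene:
    """Read a mono WAV into an AudioScene (integer PCM scaled to [-1, 1])."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return AudioScene(samples=np.asarray(data, dtype=np.float64), sample_rate=int(rate),
                      scene_id=Path(path).stem)


def write_annotations(path: str | Path, events: list[SceneEvent]) -> None:
    """Tab-separated sidecar: onset_s, category, level_db, duration_s."""
    pd.DataFrame([{"onset_s": e.onset_s, "category": e.category,
                   "level_db": e.level_db, "duration_s": e.duration_s}
                  for e in events]).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[SceneEvent]:
    df = pd.read_csv(path, sep="\t")
    return [SceneEvent(onset_s=float(r.onset_s), category=str(r.category),
                       level_db=float(r.level_db), duration_s=float(r.duration_s))
            for r in df.itertuples()]


def write_events(path: str | Path, events: list[SalientEvent],
                 scene_id: str = "scene") -> None:
    """Tab-separated detected events: scene, time_s, strength, category."""
    pd.DataFrame([{"scene": scene_id, "time_s": e.time_s, "strength": e.strength,
                   "category": e.category} for e in events]).to_csv(
        path, sep="\t", index=False)


def read_events(path: str | Path) -> list[SalientEvent]:
    df = pd.read_csv(path, sep="\t")
    return [SalientEvent(time_s=float(r.time_s), strength=float(r.strength),
                         category=str(r.category)) for r in df.itertuples()]


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_tracks(path: str | Path, tracks: dict[str, np.ndarray],
                 rate: float) -> None:
    """Named time-series tracks, one row per sample, with a time column."""
    n = len(next(iter(tracks.values())))
    df = pd.DataFrame({"time_s": np.arange(n) / rate, **tracks})
    df.to_csv(path, sep="\t", index=False)
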