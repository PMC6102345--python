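"""Synthetic study generator: scenes, attention data, and band-energy surrogates.

Every downstream stage of the pipeline is tested by parameter recovery on
data produced here, because the original soundscape recordings and the
behavioral/EEG responses to them are not available.  Three generators cover
the three measurement domains:

* :func:`gen_scene` builds mono audio scenes (default 2 min at 22,050 Hz) as
  1/f background noise plus parametric event tokens of known onset and
  category (speech-like harmonic complexes with a pitch contour, note
  sequences, vocal glides, band-limited vehicle noise swells, impulsive
  tapping bursts).  Scenes come in a sparse and a dense flavor; dense scenes
  carry at least three times the event rate of sparse ones.
* :func:`gen_salience` simulates listeners as two-state (attend / ignore)
  Markov chains sampled at 10 Hz whose switch-to-attend hazard is boosted in
  a window after each event, shifted by the motor-response delay.  The
  percentage attending is the behavioral salience curve.
* :func:`gen_band_energy` plants a lag-shifted, weighted copy of a driver
  signal (e.g. a surprisal track) in each channel x band track plus Gaussian
  noise, so lag- and weight-recovery by the correlation machinery can be
  verified exactly.  :func:`gen_raw_eeg` additionally synthesizes raw
  multichannel signals (band-centered carriers amplitude-modulated by the
  driver) to exercise the spectral path of the EEG module.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .behavior import SalienceCurve
from .eeg import DEFAULT_BANDS, BandEnergySeries
from .scene import AudioScene, SceneEvent

SYNTH_CATEGORIES = ("speech", "music", "vocal", "vehicle", "tapping")

#: Event rates (events per second) defining the sparse / dense convention;
#: dense is >= 3x sparse.
SPARSE_EVENT_RATE = 0.05
DENSE_EVENT_RATE = 0.20


@dataclass
class SceneConfig:
    """Recipe for one synthetic scene."""

    duration_s: float = 120.0
    sample_rate: int = 22050
    density: str = "sparse"
    event_specs: list[tuple[float, str, float, float]] = field(default_factory=list)
    background_level_db: float = -40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.density not in ("sparse", "dense"):
            raise ValueError("density must be 'sparse' or 'dense'")
        for onset, category, _level, dur in self.event_specs:
            if category not in SYNTH_CATEGORIES:
                raise ValueError(f"cannot synthesize category {category!r}")
            if onset < 0 or onset >= self.duration_s:
                raise ValueError(f"event onset {onset} outside [0, {self.duration_s})")
            if onset + dur > self.duration_s:
                raise ValueError(f"event at {onset}s extends beyond the scene")


@dataclass
class SubjectModel:
    """Two-state Markov listeners producing a percent-attending curve."""

    n_subjects: int = 20
    switch_prob_base: float = 0.05   # per second, both directions
    event_gain: float = 20.0         # multiplicative boost to switch-to-attend
    motor_delay_s: float = 1.4
    event_window_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not 0.0 <= self.switch_prob_base <= 1.0:
            raise ValueError("switch probability must be in [0, 1]")
        if self.event_gain < 0:
            raise ValueError("event gain must be non-negative")


@dataclass
class EEGMixConfig:
    """Planted-correlation recipe for band-energy surrogates."""

    n_channels: int = 4
    band_weights: dict[str, float] = field(
        default_factory=lambda: {name: 0.0 for name in DEFAULT_BANDS})
    planted_lag_s: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if abs(self.planted_lag_s) > 3.0:
            raise ValueError("planted lag must be within +/- 3 s")


# ---------------------------------------------------------------------------
# audio scene synthesis

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-power noise via spectral shaping, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec = spec / np.sqrt(freqs)
    x = np.fft.irfft(spec, n=n)
    return x / np.sqrt(np.mean(x ** 2))


def _harmonic_tone(f0: np.ndarray, rate: int, n_harmonics: int = 10) -> np.ndarray:
    phase = 2 * np.pi * np.cumsum(f0) / rate
    out = np.zeros_like(phase)
    for h in range(1, n_harmonics + 1):
        out += np.sin(h * phase) / h
    return out


def _event_token(category: str, duration_s: float, rate: int,
                 rng: np.random.Generator) -> np.ndarray:
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    if category == "speech":
        # harmonic complex with a wandering pitch contour and ~4 Hz syllabic AM
        contour = 120.0 * 2 ** np.cumsum(rng.normal(0, 0.004, n))
        contour = np.clip(contour, 80.0, 250.0)
        tone = _harmonic_tone(contour, rate, n_harmonics=12)
        am = 0.5 + 0.5 * np.sin(2 * np.pi * 4.0 * t + rng.uniform(0, 2 * np.pi))
        x = tone * am
    elif category == "music":
        # sequence of pentatonic notes with decaying envelopes
        scale = 220.0 * 2 ** (np.array([0, 2, 4, 7, 9]) / 12.0)
        note_len = max(1, int(0.25 * rate))
        x = np.zeros(n)
        pos = 0
        while pos < n:
            f = rng.choice(scale) * rng.choice([1.0, 2.0])
            seg = min(note_len, n - pos)
            tt = np.arange(seg) / rate
            env = np.exp(-tt / 0.15)
            x[pos:pos + seg] = env * _harmonic_tone(np.full(seg, f), rate, 6)
            pos += seg
    elif category == "vocal":
        # single glide with strong vibrato
        f0 = np.linspace(200.0, 400.0, n) * (1 + 0.03 * np.sin(2 * np.pi * 6.0 * t))
        x = _harmonic_tone(f0, rate, n_harmonics=8)
    elif category == "vehicle":
        # band-limited noise swell
        sos = sps.butter(4, [60.0, 300.0], btype="bandpass", fs=rate, output="sos")
        x = sps.sosfilt(sos, rng.standard_normal(n))
        x = x * np.hanning(n)
    elif category == "tapping":
        # impulsive decaying-noise bursts at ~4 Hz
        x = np.zeros(n)
        burst = int(0.03 * rate)
        period = int(0.25 * rate)
        for pos in range(0, n - burst, period):
            x[pos:pos + burst] += rng.standard_normal(burst) * np.exp(
                -np.arange(burst) / (0.005 * rate))
    else:  # pragma: no cover - guarded by SceneConfig validation
        raise ValueError(f"cannot synthesize category {category!r}")
    rms = np.sqrt(np.mean(x ** 2))
    if rms > 0:
        x = x / rms
    ramp = max(1, int(0.01 * rate))
    x[:ramp] *= np.linspace(0, 1, ramp)
    x[-ramp:] *= np.linspace(1, 0, ramp)
    return x


def _db_to_amplitude(level_db: float) -> float:
    if np.isneginf(level_db):
        return 0.0
    return 10.0 ** (level_db / 20.0)


def gen_scene(config: SceneConfig) -> AudioScene:
    """Render a scene: 1/f background plus event tokens at annotated onsets."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.sample_rate))
    bg_amp = _db_to_amplitude(config.background_level_db)
    x = _pink_noise(n, rng) * bg_amp if bg_amp > 0 else np.zeros(n)
    annotations = []
    for onset, category, level_db, dur in config.event_specs:
        token = _event_token(category, dur, config.sample_rate, rng)
        token = token * _db_to_amplitude(level_db)
        start = int(round(onset * config.sample_rate))
        x[start:start + token.size] += token
        annotations.append(SceneEvent(onset_s=onset, category=category,
                                      level_db=level_db, duration_s=dur))
    return AudioScene(samples=x, sample_rate=config.sample_rate,
                      annotations=annotations,
                      scene_id=f"{config.density}-{config.seed}")


def random_scene_config(density: str = "sparse", duration_s: float = 120.0,
                        sample_rate: int = 22050, seed: int = 0,
                        event_level_db: float = -10.0,
                        event_duration_s: float = 1.5,
                        background_level_db: float = -40.0) -> SceneConfig:
    """Draw non-overlapping events at the sparse or dense rate convention."""
    rng = np.random.default_rng(seed)
    rate = SPARSE_EVENT_RATE if density == "sparse" else DENSE_EVENT_RATE
    n_events = max(1, int(round(rate * duration_s)))
    margin = event_duration_s + 2.0
    # non-overlapping onsets: jittered grid over the usable interval
    grid = np.linspace(2.0, duration_s - margin, n_events)
    slack = (grid[1] - grid[0]) / 3.0 if n_events > 1 else duration_s / 4.0
    onsets = np.sort(np.clip(grid + rng.uniform(-slack, slack, n_events),
                             2.0, duration_s - margin))
    specs = [(float(t), str(rng.choice(SYNTH_CATEGORIES)), event_level_db,
              event_duration_s) for t in onsets]
    return SceneConfig(duration_s=duration_s, sample_rate=sample_rate,
                       density=density, event_specs=specs,
                       background_level_db=background_level_db, seed=seed)


# ---------------------------------------------------------------------------
# simulated listeners

def gen_attention(scene: AudioScene, subjects: SubjectModel,
                  rate: float = 10.0) -> np.ndarray:
    """Simulate the subjects x time binary attention matrix at 10 Hz."""
    if scene.annotations is None:
        raise ValueError("scene must carry ground-truth events")
    rng = np.random.default_rng(subjects.seed)
    n = int(round(scene.duration_s * rate))
    dt = 1.0 / rate
    p_base = 1.0 - (1.0 - subjects.switch_prob_base) ** dt
    t_axis = np.arange(n) * dt
    boost = np.zeros(n, dtype=bool)
    for ev in scene.annotations:
        lo = ev.onset_s + subjects.motor_delay_s
        hi = lo + subjects.event_window_s
        boost |= (t_axis >= lo) & (t_axis < hi)
    p_attend = np.where(boost, np.minimum(1.0, p_base * (1.0 + subjects.event_gain)),
                        p_base)
    attention = np.zeros((subjects.n_subjects, n), dtype=np.int8)
    state = rng.random(subjects.n_subjects) < 0.5
    u = rng.random((subjects.n_subjects, n))
    for i in range(n):
        switch_on = (~state) & (u[:, i] < p_attend[i])
        switch_off = state & (u[:, i] < p_base)
        state = (state | switch_on) & ~switch_off
        attention[:, i] = state
    return attention


def gen_salience(scene: AudioScene, subjects: SubjectModel,
                 rate: float = 10.0) -> SalienceCurve:
    """Percent-attending curve from the simulated attention matrix."""
    attention = gen_attention(scene, subjects, rate=rate)
    return SalienceCurve(values=attention.mean(axis=0) * 100.0, rate=rate,
                         scene_id=scene.scene_id)


# ---------------------------------------------------------------------------
# band-energy surrogates and raw EEG

def _shift(x: np.ndarray, lag_samples: int) -> np.ndarray:
    """Shift so the output FOLLOWS the input by ``lag_samples`` (edge-padded)."""
    if lag_samples == 0:
        return x.copy()
    out = np.empty_like(x)
    if lag_samples > 0:
        out[lag_samples:] = x[:-lag_samples]
        out[:lag_samples] = x[0]
    else:
        out[:lag_samples] = x[-lag_samples:]
        out[lag_samples:] = x[-1]
    return out


def gen_band_energy(driver: np.ndarray, mix: EEGMixConfig,
                    rate: float = 10.0) -> BandEnergySeries:
    """Band-energy surrogate: weighted lag-shifted driver + noise, z-scored.

    The driver must be sampled at 10 Hz.  Ground-truth lag and weights are
    stored on the returned series.
    """
    rng = np.random.default_rng(mix.seed)
    d = np.asarray(driver, dtype=np.float64)
    d = (d - d.mean()) / (d.std() if d.std() > 0 else 1.0)
    lag = int(round(mix.planted_lag_s * rate))
    shifted = _shift(d, lag)
    band_names = tuple(DEFAULT_BANDS)
    out = np.empty((mix.n_channels, len(band_names), d.size))
    for c in range(mix.n_channels):
        for b, name in enumerate(band_names):
            w = mix.band_weights.get(name, 0.0)
            track = w * shifted + mix.noise_sd * rng.standard_normal(d.size)
            sd = track.std()
            mu = track.mean()
            out[c, b] = (track - mu) / (sd if sd > 0 else 1.0)
    return BandEnergySeries(values=out, band_names=band_names, step_s=1.0 / rate,
                            ground_truth={"lag_s": mix.planted_lag_s,
                                          "weights": dict(mix.band_weights),
                                          "noise_sd": mix.noise_sd})


def gen_raw_eeg(driver: np.ndarray, driver_rate: float = 10.0,
                n_channels: int = 4, rate: float = 256.0,
                mod_depth: float = 0.8, noise_sd: float = 0.1,
                seed: int = 0) -> np.ndarray:
    """Raw multichannel surrogate: band-centered carriers AM-modulated by the
    driver, plus broadband noise — exercises the spectral path of the EEG
    module (channels x samples at ``rate``)."""
    rng = np.random.default_rng(seed)
    d = np.asarray(driver, dtype=np.float64)
    span = float(np.ptp(d))
    d = (d - d.min()) / (span if span > 0 else 1.0)  # [0, 1]
    n = int(round(d.size / driver_rate * rate))
    d_up = np.interp(np.arange(n) / rate, np.arange(d.size) / driver_rate, d)
    t = np.arange(n) / rate
    out = np.empty((n_channels, n))
    for c in range(n_channels):
        x = noise_sd * rng.standard_normal(n)
        for lo, hi in DEFAULT_BANDS.values():
            f = 0.5 * (lo + hi)
            carrier = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            x += (1.0 - mod_depth + mod_depth * d_up) * carrier / len(DEFAULT_BANDS)
        out[c] = x
    return out
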