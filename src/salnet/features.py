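"""Acoustic front-end: log-mel spectrogram and the ten acoustic feature tracks.

The mel spectrogram is the CNN input representation: 25 ms windows advanced
by 10 ms, 64 mel-spaced bands, log compressed.  All audio is resampled
internally to a single analysis rate of 16 kHz so that the window and hop
are an integer number of samples (400 and 160) and a 960 ms excerpt yields
exactly 96 frames.

The feature tracks are the classical descriptors used in auditory-salience
work: loudness, brightness (spectral centroid), bandwidth (spectral spread),
spectral flatness, spectral irregularity, pitch, harmonicity, temporal and
spectral modulation centroids (rate / scale), and roughness.  Roughness is
the average magnitude of the 30-150 Hz amplitude-modulation spectrum of a
frame, normalized by the frame's RMS energy, so it is invariant to overall
level.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .scene import AudioScene

#: Internal analysis sample rate (Hz).  25 ms / 10 ms are exact sample counts.
ANALYSIS_RATE = 16000
MEL_WINDOW_S = 0.025
MEL_HOP_S = 0.010
N_MELS = 64
#: Mel filterbank frequency range (Hz).
MEL_FMIN = 125.0
MEL_FMAX = 7500.0
#: Additive floor inside the log so digital silence maps to log(LOG_OFFSET).
LOG_OFFSET = 1e-6

#: Names of the ten acoustic feature tracks, in canonical order.
FEATURE_NAMES = (
    "loudness",
    "brightness",
    "bandwidth",
    "flatness",
    "irregularity",
    "pitch",
    "harmonicity",
    "rate",
    "scale",
    "roughness",
)


@dataclass
class MelSpectrogram:
    """Log-mel magnitude matrix, frames x 64 bands."""

    values: np.ndarray  # (n_frames, N_MELS)
    frame_hop_s: float = MEL_HOP_S
    window_s: float = MEL_WINDOW_S

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != N_MELS:
            raise ValueError(f"mel spectrogram must be frames x {N_MELS}")


@dataclass
class FeatureSeries:
    """The ten acoustic feature tracks at a common frame rate."""

    tracks: dict[str, np.ndarray]
    frame_rate: float

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.tracks)
        if missing:
            raise ValueError(f"missing feature tracks: {sorted(missing)}")
        lengths = {len(v) for v in self.tracks.values()}
        if len(lengths) != 1:
            raise ValueError("feature tracks have unequal lengths")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.tracks[name]

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.tracks.values())))


def resample_audio(x: np.ndarray, rate: float, target: float = ANALYSIS_RATE) -> np.ndarray:
    """Polyphase resampling to the analysis rate."""
    if rate == target:
        return np.asarray(x, dtype=np.float64)
    frac = Fraction(target / rate).limit_denominator(10000)
    return sps.resample_poly(np.asarray(x, dtype=np.float64), frac.numerator, frac.denominator)


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int = N_MELS, n_fft: int = 512, rate: float = ANALYSIS_RATE,
                   fmin: float = MEL_FMIN, fmax: float = MEL_FMAX) -> np.ndarray:
    """Triangular mel filterbank, (n_mels, n_fft//2 + 1)."""
    mel_edges = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_edges = mel_to_hz(mel_edges)
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, mid, hi = hz_edges[i], hz_edges[i + 1], hz_edges[i + 2]
        up = (fft_freqs - lo) / (mid - lo)
        down = (hi - fft_freqs) / (hi - mid)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def _frame_centered(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Centered frames with reflect padding; frame count = floor(N / hop).

    Frame ``k`` is centered on sample ``k * hop`` of the original signal, so
    a 960 ms excerpt at 16 kHz (15,360 samples, hop 160) gives exactly 96
    frames — the input-patch length the network expects.
    """
    if x.size < win:
        raise ValueError("signal shorter than one analysis window")
    pad = win // 2
    xp = np.pad(x, pad, mode="reflect")
    n_frames = x.size // hop
    frames = sliding_window_view(xp, win)[::hop][:n_frames]
    return frames


def compute_mel_spectrogram(scene: AudioScene) -> MelSpectrogram:
    """Log-mel spectrogram of a scene (frames x 64)."""
    x = resample_audio(scene.samples, scene.sample_rate)
    win = int(round(MEL_WINDOW_S * ANALYSIS_RATE))
    hop = int(round(MEL_HOP_S * ANALYSIS_RATE))
    if x.size < win:
        raise ValueError("scene shorter than one mel analysis window")
    frames = _frame_centered(x, win, hop)
    window = np.hanning(win)
    n_fft = 512
    spec = np.abs(np.fft.rfft(frames * window, n=n_fft, axis=1)) ** 2
    mel = spec @ mel_filterbank(n_fft=n_fft).T
    return MelSpectrogram(values=np.log(mel + LOG_OFFSET))


def _frames_left_aligned(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Left-aligned full frames: count = 1 + floor((N - win) / hop)."""
    if x.size < win:
        raise ValueError("signal shorter than one frame")
    return sliding_window_view(x, win)[::hop]


def roughness_of_frame(frame: np.ndarray, rate: float,
                       lo: float = 30.0, hi: float = 150.0) -> float:
    """Roughness of one frame.

    Amplitude envelope by the analytic-signal magnitude, mean removed, then
    the average magnitude of its modulation spectrum over ``lo``-``hi`` Hz,
    divided by the frame RMS.  A silent frame has roughness 0.
    """
    rms = float(np.sqrt(np.mean(frame ** 2)))
    if rms == 0.0:
        return 0.0
    env = np.abs(sps.hilbert(frame))
    env = env - env.mean()
    mod = np.abs(np.fft.rfft(env)) / env.size
    freqs = np.fft.rfftfreq(env.size, d=1.0 / rate)
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise ValueError("frame too short to resolve the modulation band")
    return float(np.mean(mod[band]) / rms)


def compute_roughness(scene: AudioScene, frame_s: float = 0.2,
                      hop_s: float = 0.1) -> np.ndarray:
    """Per-frame roughness track (frame >= 100 ms to resolve 30 Hz)."""
    if frame_s < 0.1:
        raise ValueError("roughness frame must be >= 100 ms to resolve 30 Hz modulation")
    x = resample_audio(scene.samples, scene.sample_rate)
    win = int(round(frame_s * ANALYSIS_RATE))
    hop = int(round(hop_s * ANALYSIS_RATE))
    frames = _frames_left_aligned(x, win, hop)
    return np.array([roughness_of_frame(f, ANALYSIS_RATE) for f in frames])


def _spectral_moments(power: np.ndarray, freqs: np.ndarray) -> tuple[float, float]:
    total = power.sum()
    if total <= 0:
        return 0.0, 0.0
    centroid = float((freqs * power).sum() / total)
    spread = float(np.sqrt(((freqs - centroid) ** 2 * power).sum() / total))
    return centroid, spread


def _autocorr_pitch(frame: np.ndarray, rate: float,
                    fmin: float = 50.0, fmax: float = 2000.0) -> tuple[float, float]:
    """Pitch (Hz) and harmonicity from the normalized autocorrelation peak."""
    frame = frame - frame.mean()
    denom = float(np.dot(frame, frame))
    if denom == 0.0:
        return 0.0, 0.0
    ac = sps.correlate(frame, frame, mode="full")[frame.size - 1:]
    ac = ac / denom
    lag_lo = max(2, int(rate / fmax))
    lag_hi = min(frame.size - 1, int(rate / fmin))
    if lag_hi <= lag_lo:
        return 0.0, 0.0
    seg = ac[lag_lo:lag_hi]
    k = int(np.argmax(seg))
    return rate / (lag_lo + k), float(seg[k])


def _modulation_centroids(logmel_block: np.ndarray, frame_rate: float) -> tuple[float, float]:
    """Energy centroids of the temporal (rate) and spectral (scale) modulation
    spectra of a log-mel block (mel frames x bands)."""
    block = logmel_block - logmel_block.mean()
    mod = np.abs(np.fft.fft2(block)) ** 2
    nt, nf = block.shape
    tfreq = np.abs(np.fft.fftfreq(nt, d=1.0 / frame_rate))  # Hz
    sfreq = np.abs(np.fft.fftfreq(nf))  # cycles per mel band
    rate_profile = mod.sum(axis=1)
    scale_profile = mod.sum(axis=0)
    rt = rate_profile.sum()
    st = scale_profile.sum()
    rate_c = float((tfreq * rate_profile).sum() / rt) if rt > 0 else 0.0
    scale_c = float((sfreq * scale_profile).sum() / st) if st > 0 else 0.0
    return rate_c, scale_c


def compute_acoustic_features(scene: AudioScene, frame_s: float = 0.2,
                              hop_s: float = 0.1) -> FeatureSeries:
    """All ten acoustic feature tracks at a common frame rate (default 10 Hz)."""
    x = resample_audio(scene.samples, scene.sample_rate)
    win = int(round(frame_s * ANALYSIS_RATE))
    hop = int(round(hop_s * ANALYSIS_RATE))
    frames = _frames_left_aligned(x, win, hop)
    n = frames.shape[0]

    window = np.hanning(win)
    spec = np.abs(np.fft.rfft(frames * window, axis=1))
    power = spec ** 2
    freqs = np.fft.rfftfreq(win, d=1.0 / ANALYSIS_RATE)

    eps = 1e-12
    loudness = 20.0 * np.log10(np.sqrt(np.mean(frames ** 2, axis=1)) + eps)

    brightness = np.empty(n)
    bandwidth = np.empty(n)
    for i in range(n):
        brightness[i], bandwidth[i] = _spectral_moments(power[i], freqs)

    # flatness: geometric / arithmetic mean of the power spectrum; the log
    # floor is relative to the frame's peak so the measure is scale invariant
    peak = power.max(axis=1, keepdims=True)
    floor = np.where(peak > 0, peak, 1.0) * 1e-12
    flatness = (np.exp(np.mean(np.log(power + floor), axis=1))
                / (np.mean(power, axis=1) + floor[:, 0]))

    # irregularity: normalized squared successive spectral-bin differences
    num = np.sum(np.diff(spec, axis=1) ** 2, axis=1)
    den = np.sum(spec ** 2, axis=1) + eps
    irregularity = num / den

    pitch = np.empty(n)
    harmonicity = np.empty(n)
    for i in range(n):
        pitch[i], harmonicity[i] = _autocorr_pitch(frames[i], ANALYSIS_RATE)

    # rate / scale from log-mel blocks covering each feature frame
    mel = compute_mel_spectrogram(scene).values
    mel_rate = 1.0 / MEL_HOP_S
    block_len = max(2, int(round(frame_s * mel_rate)))
    hop_mel = int(round(hop_s * mel_rate))
    rate_track = np.zeros(n)
    scale_track = np.zeros(n)
    for i in range(n):
        start = i * hop_mel
        block = mel[start:start + block_len]
        if block.shape[0] >= 2:
            rate_track[i], scale_track[i] = _modulation_centroids(block, mel_rate)
        elif i > 0:
            rate_track[i], scale_track[i] = rate_track[i - 1], scale_track[i - 1]

    roughness = np.array([roughness_of_frame(f, ANALYSIS_RATE) for f in frames])

    tracks = {
        "loudness": loudness,
        "brightness": brightness,
        "bandwidth": bandwidth,
        "flatness": flatness,
        "irregularity": irregularity,
        "pitch": pitch,
        "harmonicity": harmonicity,
        "rate": rate_track,
        "scale": scale_track,
        "roughness": roughness,
    }
    return FeatureSeries(tracks=tracks, frame_rate=1.0 / hop_s)
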