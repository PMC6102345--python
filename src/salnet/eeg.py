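"""EEG band energies: sliding-window spectra, z-scoring and electrode groups.

Multichannel signals (assumed already cleaned of line noise and blink
artifacts upstream) are reduced to six canonical band-energy tracks per
channel: Delta (1-4 Hz), Theta (4-7), Alpha (8-15), Beta (15-30), Gamma
(30-50) and High Gamma (70-110).  Energy is the mean power over the band's
frequency bins of a Hann-tapered Fourier transform in 1 s windows advanced
by 100 ms, z-scored per channel and band over the scene.  Channels carry
group labels (e.g. ``frontal`` for electrodes near Fz, ``central`` near Cz)
so activity can be averaged per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

#: The six analysis bands, low to high (name -> (lo, hi) in Hz).
DEFAULT_BANDS = {
    "Delta": (1.0, 4.0),
    "Theta": (4.0, 7.0),
    "Alpha": (8.0, 15.0),
    "Beta": (15.0, 30.0),
    "Gamma": (30.0, 50.0),
    "HighGamma": (70.0, 110.0),
}

#: Standard working rate for raw signals (Hz).
EEG_RATE = 256.0


@dataclass
class BandEnergySeries:
    """Per-channel, per-band z-scored energy; values are (channels, bands, time)."""

    values: np.ndarray
    band_names: tuple[str, ...]
    step_s: float = 0.1
    group_labels: tuple[str, ...] | None = None
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[1] != len(self.band_names):
            raise ValueError("values must be channels x bands x time")
        if self.group_labels is not None and len(self.group_labels) != self.values.shape[0]:
            raise ValueError("one group label per channel required")

    @property
    def rate(self) -> float:
        return 1.0 / self.step_s

    def band(self, name: str) -> np.ndarray:
        return self.values[:, self.band_names.index(name), :]


def preprocess(signal: np.ndarray, rate: float, target_rate: float = EEG_RATE) -> np.ndarray:
    """Demean, linearly detrend, and resample each channel to the working rate."""
    x = sps.detrend(np.asarray(signal, dtype=np.float64), axis=-1, type="linear")
    if rate != target_rate:
        frac = Fraction(target_rate / rate).limit_denominator(10000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return x


def rereference_common_average(signal: np.ndarray) -> np.ndarray:
    """Subtract the per-sample mean across channels from every channel."""
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a channels x samples matrix with >= 2 channels")
    return x - x.mean(axis=0, keepdims=True)


def band_energy(signal: np.ndarray, rate: float,
                bands: dict[str, tuple[float, float]] | None = None,
                window_s: float = 1.0, step_s: float = 0.1,
                group_labels: tuple[str, ...] | None = None,
                zscore: bool = True) -> BandEnergySeries:
    """Sliding-window band power per channel, z-scored per channel and band.

    ``zscore=False`` returns raw mean band power (always non-negative),
    useful for inspecting the spectral content before normalization.
    """
    bands = bands or DEFAULT_BANDS
    x = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    nyquist = rate / 2.0
    for name, (lo, hi) in bands.items():
        if lo >= hi:
            raise ValueError(f"band {name}: lo must be < hi")
        if hi > nyquist:
            raise ValueError(f"sampling rate {rate} Hz too low for band {name} "
                             f"({lo}-{hi} Hz)")
    win = int(round(window_s * rate))
    n = x.shape[1]
    if n < win:
        raise ValueError("signal shorter than one analysis window")
    # window starts live on the step_s time grid; each is rounded to the
    # nearest sample so the output rate is exactly 1/step_s even when
    # step_s * rate is not an integer (e.g. 25.6 samples at 256 Hz)
    n_windows = int(np.floor((n / rate - window_s) / step_s)) + 1
    starts = np.round(np.arange(n_windows) * step_s * rate).astype(int)
    taper = np.hanning(win)
    freqs = np.fft.rfftfreq(win, d=1.0 / rate)
    band_bins = {name: (freqs >= lo) & (freqs <= hi) for name, (lo, hi) in bands.items()}
    out = np.empty((x.shape[0], len(bands), starts.size))
    for c in range(x.shape[0]):
        frames = np.stack([x[c, s: s + win] * taper for s in starts])
        power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
        for b, name in enumerate(bands):
            out[c, b] = power[:, band_bins[name]].mean(axis=1)
    if zscore:
        mu = out.mean(axis=2, keepdims=True)
        sd = out.std(axis=2, keepdims=True)
        sd[sd == 0.0] = 1.0
        out = (out - mu) / sd
    return BandEnergySeries(values=out, band_names=tuple(bands),
                            step_s=step_s, group_labels=group_labels)


def group_average(series: BandEnergySeries, group: str) -> np.ndarray:
    """Mean band-energy over channels in a group; (bands, time).

    ``group='all'`` averages every channel regardless of labels.
    """
    if group == "all":
        return series.values.mean(axis=0)
    if series.group_labels is None:
        raise ValueError("series has no group labels")
    mask = np.array([g == group for g in series.group_labels])
    if not mask.any():
        raise ValueError(f"no channels labeled {group!r}")
    return series.values[mask].mean(axis=0)
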