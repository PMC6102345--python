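"""Common conditioning of continuous signals and lagged correlation measures.

Every continuous signal entering a correlation — surprisal, acoustic
feature, salience curve, band energy — is conditioned identically:
resampled to 10 Hz, truncated to at most 120 s, the first 2 s dropped (to
avoid trial-onset transients), then band-limited to [1/30, 1/6] Hz with
fourth-order Butterworth high- and low-pass filters applied forward and
backward (zero phase, so the filters add no hidden delay to the explicit
lag search).

Correlations are normalized sliding dot products (Pearson on the
overlapping region) evaluated at every integer-sample lag within +/- 3 s;
the maximum and its lag are reported.  Positive lag means the second signal
follows the first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy import stats

from .behavior import SalientEvent

#: Common analysis rate after conditioning (Hz).
CONDITIONED_RATE = 10.0
#: Band limits of the conditioning filters (Hz).
HIGHPASS_HZ = 1.0 / 30.0
LOWPASS_HZ = 1.0 / 6.0
#: Seconds removed from the start of every scene.
TRIM_S = 2.0
#: Maximum scene length kept before trimming (s).
MAX_LEN_S = 120.0


@dataclass
class ConditionedSeries:
    """A 10 Hz band-limited series; sample 0 sits at scene time ``t0_s``."""

    values: np.ndarray
    origin: str = "feature"  # surprisal | feature | salience | band
    scene_id: str = "scene"
    rate: float = CONDITIONED_RATE
    t0_s: float = TRIM_S

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate

    def time_to_index(self, t_s: float) -> int:
        return int(round((t_s - self.t0_s) * self.rate))


@dataclass
class LagCorrelation:
    r: float
    lag_s: float
    defined: bool = True


def butterworth_band_gain(freqs_hz: np.ndarray, order: int = 4) -> np.ndarray:
    """Zero-phase power gain of the conditioning band filters.

    Forward-backward application of an order-4 Butterworth filter has the
    squared magnitude response and no phase; the combined high-pass (1/30
    Hz) and low-pass (1/6 Hz) gain is ``|H_hp|^2 * |H_lp|^2`` with
    ``|H|^2 = 1 / (1 + (f/fc)^(2*order))``.
    """
    f = np.asarray(freqs_hz, dtype=np.float64)
    lp = 1.0 / (1.0 + (f / LOWPASS_HZ) ** (2 * order))
    with np.errstate(divide="ignore"):
        ratio = np.where(f > 0, HIGHPASS_HZ / np.where(f > 0, f, 1.0), np.inf)
    hp = 1.0 / (1.0 + ratio ** (2 * order))
    hp[f == 0] = 0.0
    return lp * hp


def _zero_phase_bandlimit(x: np.ndarray, rate: float) -> np.ndarray:
    """Apply the zero-phase Butterworth band gain spectrally.

    The gain is applied to the DFT of the linearly detrended signal, which
    sidesteps the long warm-up transients a recursive implementation of
    these very low cutoffs (30 s high-pass period vs a 118 s signal) would
    spread through the series.  Detrending removes the wrap-around step the
    circular transform would otherwise turn into in-band leakage; the trend
    lies below the high-pass band and would be removed regardless.
    """
    x = sps.detrend(x, type="linear")
    gain = butterworth_band_gain(np.fft.rfftfreq(x.size, d=1.0 / rate))
    return np.fft.irfft(np.fft.rfft(x) * gain, n=x.size)


def condition(values: np.ndarray, rate: float, origin: str = "feature",
              scene_id: str = "scene") -> ConditionedSeries:
    """Resample to 10 Hz, truncate/trim, and band-limit to [1/30, 1/6] Hz."""
    x = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input series")
    if x.size / rate < 5.0:
        raise ValueError("series shorter than 5 s")
    if rate != CONDITIONED_RATE:
        frac = Fraction(CONDITIONED_RATE / rate).limit_denominator(10000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
    x = x[: int(round(MAX_LEN_S * CONDITIONED_RATE))]
    x = x[int(round(TRIM_S * CONDITIONED_RATE)):]
    x = _zero_phase_bandlimit(x, CONDITIONED_RATE)
    return ConditionedSeries(values=x, origin=origin, scene_id=scene_id)


def max_lagged_correlation(x: ConditionedSeries | np.ndarray,
                           y: ConditionedSeries | np.ndarray,
                           max_lag_s: float = 3.0,
                           rate: float = CONDITIONED_RATE,
                           min_overlap_s: float = 10.0) -> LagCorrelation:
    """Maximum Pearson correlation over integer-sample lags in +/- max_lag_s.

    Positive lag means ``y`` follows ``x`` (y is a delayed copy).
    """
    if isinstance(x, ConditionedSeries):
        rate = x.rate
        x = x.values
    if isinstance(y, ConditionedSeries):
        if y.rate != rate:
            raise ValueError("series rates differ")
        y = y.values
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    max_lag = int(round(max_lag_s * rate))
    n = min(x.size, y.size)
    if (n - max_lag) / rate < min_overlap_s:
        raise ValueError("insufficient overlap at the maximum lag")
    best_r, best_lag = -np.inf, 0
    any_defined = False
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            xs, ys = x[: n - lag], y[lag:n]
        else:
            xs, ys = x[-lag:n], y[: n + lag]
        if xs.std() == 0.0 or ys.std() == 0.0:
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        any_defined = True
        if r > best_r:
            best_r, best_lag = r, lag
    if not any_defined:
        return LagCorrelation(r=np.nan, lag_s=np.nan, defined=False)
    return LagCorrelation(r=best_r, lag_s=best_lag / rate)


@dataclass
class EventWindowCorrelation:
    """Per-event correlations around salient events, plus bookkeeping."""

    per_event_r: np.ndarray
    mean_r: float
    n_skipped: int
    event_times: np.ndarray = field(default_factory=lambda: np.array([]))


def windowed_event_correlation(surprisal: ConditionedSeries,
                               salience: ConditionedSeries,
                               events: list[SalientEvent],
                               delay_s: float = 1.4,
                               half_window_s: float = 3.0) -> EventWindowCorrelation:
    """Correlate surprisal with motor-delayed salience around each event.

    For an event at scene time t the surprisal window is [t - 3, t + 3] and
    the salience window is the same interval shifted by ``delay_s`` (the
    motor-response delay of the behavioral task).
    """
    rate = surprisal.rate
    half = int(round(half_window_s * rate))
    delay = int(round(delay_s * rate))
    rs, times = [], []
    n_skipped = 0
    for ev in events:
        c_s = surprisal.time_to_index(ev.time_s)
        c_b = salience.time_to_index(ev.time_s) + delay
        if (c_s - half < 0 or c_s + half >= surprisal.values.size
                or c_b - half < 0 or c_b + half >= salience.values.size):
            n_skipped += 1
            continue
        a = surprisal.values[c_s - half: c_s + half + 1]
        b = salience.values[c_b - half: c_b + half + 1]
        if a.std() == 0.0 or b.std() == 0.0:
            n_skipped += 1
            continue
        rs.append(float(np.corrcoef(a, b)[0, 1]))
        times.append(ev.time_s)
    rs = np.asarray(rs)
    mean_r = float(rs.mean()) if rs.size else np.nan
    return EventWindowCorrelation(per_event_r=rs, mean_r=mean_r,
                                  n_skipped=n_skipped,
                                  event_times=np.asarray(times))


def permutation_pvalue(per_event_r: np.ndarray, surprisal: ConditionedSeries,
                       salience: ConditionedSeries, events: list[SalientEvent],
                       n_shuffles: int = 1000, seed: int = 0,
                       delay_s: float = 1.4, half_window_s: float = 3.0) -> float:
    """One-sided p-value for the mean event-window correlation.

    The null circularly shifts the salience series by a random offset
    before recomputing the event windows.  Shifting preserves both
    signals' autocorrelation (the band limit makes them smooth, so window
    correlations are large in magnitude everywhere) while destroying any
    time-locked relation between them, which is the effect under test.
    """
    rng = np.random.default_rng(seed)
    observed = float(np.mean(per_event_r))
    n = salience.values.size
    count = 0
    for _ in range(n_shuffles):
        shift = int(rng.integers(1, n))
        shifted = ConditionedSeries(values=np.roll(salience.values, shift),
                                    origin=salience.origin,
                                    scene_id=salience.scene_id,
                                    t0_s=salience.t0_s)
        res = windowed_event_correlation(surprisal, shifted, events,
                                         delay_s=delay_s,
                                         half_window_s=half_window_s)
        if res.per_event_r.size and res.mean_r >= observed:
            count += 1
    return (count + 1) / (n_shuffles + 1)
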