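"""Shared derivative-and-smooth primitive.

Both salient-event detection and the event-prediction feature slopes use
the same operation: first difference of a track, then repeated passes of an
equally weighted centered moving average.
"""

from __future__ import annotations

import numpy as np


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Equally weighted centered moving average, same length as the input.

    Edges are handled by edge-replicating the signal before convolving, so
    interior samples are the exact boxcar mean and edge samples do not decay
    toward zero.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return np.asarray(x, dtype=np.float64).copy()
    pad = window // 2
    xp = np.pad(np.asarray(x, dtype=np.float64), pad, mode="edge")
    kernel = np.full(window, 1.0 / window)
    out = np.convolve(xp, kernel, mode="same")[pad: pad + len(x)]
    return out


def smoothed_derivative(track: np.ndarray, rate: float, window: int = 5,
                        passes: int = 3) -> np.ndarray:
    """First difference scaled to units/second, then ``passes`` moving averages.

    The result has the same length as the input (the first difference is
    prepended with its own first value).
    """
    track = np.asarray(track, dtype=np.float64)
    if track.size < 3:
        raise ValueError("track must have at least 3 samples")
    d = np.diff(track) * rate
    d = np.concatenate([[d[0]], d])
    for _ in range(passes):
        d = moving_average(d, window)
    return d
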