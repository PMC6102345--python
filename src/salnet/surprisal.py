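"""Network surprisal: distance of current layer activity from its recent past.

Surprisal at time t is the Euclidean distance between the activation vector
at t and the element-wise mean of the activation vectors in the strictly
preceding history window (default 4 s).  A constant activation pattern
therefore yields zero surprisal, while a change in the pattern sustained
over seconds yields large surprisal that decays as the new pattern fills
the history.

Frames with less than ``min_history_s`` of preceding activity are undefined
(NaN); frames with at least that much but less than the full window use the
mean of whatever history is available.  The downstream conditioning step
discards the first 2 s of every scene, which covers the default 1 s
undefined head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnn import LayerActivationSeries


@dataclass
class SurprisalSeries:
    """Scalar surprisal per frame for one layer; NaN where undefined."""

    layer_name: str
    values: np.ndarray
    frame_rate: float
    history_window_s: float = 4.0

    def defined(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]

    def filled(self) -> np.ndarray:
        """Values with the undefined head back-filled from the first defined
        frame — convenient for fixed-length conditioning, where the head
        falls inside the discarded first 2 s."""
        out = self.values.copy()
        idx = np.flatnonzero(~np.isnan(out))
        if idx.size == 0:
            raise ValueError("surprisal series has no defined frames")
        out[: idx[0]] = out[idx[0]]
        return out


def compute_surprisal(acts: LayerActivationSeries, history_window_s: float = 4.0,
                      min_history_s: float = 1.0) -> SurprisalSeries:
    """Euclidean distance of each frame from the mean of its history window.

    The history is the strict past: frames in [t - history_window_s, t),
    excluding the current frame.
    """
    frames = np.asarray(acts.frames, dtype=np.float64)
    if frames.size == 0 or frames.shape[0] == 0:
        raise ValueError("empty activation series")
    rate = acts.frame_rate
    h = int(round(history_window_s * rate))
    m = int(round(min_history_s * rate))
    if frames.shape[0] <= m:
        raise ValueError("activation series shorter than the minimum history")
    n = frames.shape[0]
    values = np.full(n, np.nan)
    window_sum = np.zeros(frames.shape[1])
    for t in range(n):
        lo = max(0, t - h)
        count = t - lo
        if count >= m:
            values[t] = np.linalg.norm(frames[t] - window_sum / count)
        # slide window: add frame t, drop frame t - h once it leaves the window
        window_sum += frames[t]
        if t - h >= 0:
            window_sum -= frames[t - h]
    return SurprisalSeries(layer_name=acts.layer_name, values=values,
                           frame_rate=rate, history_window_s=history_window_s)
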