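"""Layerwise analysis: trends, cumulative variance explained, and contrasts.

Metrics computed per network layer (correlations with acoustic features,
salience, or band energies) are summarized three ways:

* :func:`layer_trend` — ordinary least squares of the metric on layer depth
  (index 0..5 for Pool2..Embed), pooling replicates; reports the slope, its
  t statistic, degrees of freedom, p value and 99% confidence interval.
* :func:`cumulative_variance` — sequential residual regression: regress the
  salience signal on the shallowest layer's surprisal, keep the residual,
  regress it on the next layer, and so on; after layer k the cumulative
  variance explained is 1 - var(residual_k) / var(original).  Each step is
  a simple one-predictor regression, so the measure isolates the
  complementary contribution of each successive layer.
* :func:`random_baseline` — the same procedure with every layer after the
  first replaced by seeded standard-normal noise, giving the chance level
  of improvement from merely adding regressors.
* :func:`compare_groups` — per-layer differences between two conditions
  (e.g. dense vs sparse scenes) and a two-sample t test of early-layer
  (Pool2, Pool3, Conv4) vs deep-layer (Pool4, FC1, Embed) mean differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cnn import ANALYZED_LAYERS

EARLY_LAYERS = ANALYZED_LAYERS[:3]
DEEP_LAYERS = ANALYZED_LAYERS[3:]


@dataclass
class LayerMetricProfile:
    """A metric per layer with replicates; values is (n_layers, n_replicates)."""

    values: np.ndarray
    layers: tuple[str, ...] = ANALYZED_LAYERS

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[0] != len(self.layers):
            raise ValueError("one row of replicates per layer required")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=1)


@dataclass
class TrendResult:
    slope: float
    t: float
    df: int
    p: float
    ci99: tuple[float, float]
    intercept: float = 0.0


def layer_trend(profile: LayerMetricProfile) -> TrendResult:
    """OLS slope of the metric on layer index, pooling all replicates."""
    n_layers, n_rep = profile.values.shape
    if n_layers < 2 or n_rep < 2:
        raise ValueError("need >= 2 layers and >= 2 replicates")
    idx = np.repeat(np.arange(n_layers), n_rep).astype(float)
    y = profile.values.ravel()
    model = sm.OLS(y, sm.add_constant(idx)).fit()
    # degenerate exact fits: the t statistic is 0/0 noise; report the limit
    scale = max(np.abs(y).max(), 1.0)
    if np.sqrt(model.ssr / y.size) < 1e-12 * scale:
        slope = float(model.params[1])
        exact_zero = abs(slope) < 1e-12 * scale
        return TrendResult(slope=slope, t=0.0 if exact_zero else np.inf,
                           df=int(model.df_resid), p=1.0 if exact_zero else 0.0,
                           ci99=(slope, slope), intercept=float(model.params[0]))
    ci = model.conf_int(alpha=0.01)[1]
    return TrendResult(slope=float(model.params[1]), t=float(model.tvalues[1]),
                       df=int(model.df_resid), p=float(model.pvalues[1]),
                       ci99=(float(ci[0]), float(ci[1])),
                       intercept=float(model.params[0]))


def _regress_out(target: np.ndarray, predictor: np.ndarray) -> np.ndarray:
    """Residual of a simple (one-predictor, with intercept) regression."""
    x = np.column_stack([np.ones_like(predictor), predictor])
    beta, *_ = np.linalg.lstsq(x, target, rcond=None)
    return target - x @ beta


def cumulative_variance(salience: np.ndarray,
                        surprisal_by_layer: list[np.ndarray]) -> np.ndarray:
    """Cumulative fraction of salience variance explained, layer by layer.

    Layers must be ordered shallow to deep; each regression uses the
    previous residual as its target, so the fractions are non-decreasing
    and bounded by 1.
    """
    target = np.asarray(salience, dtype=np.float64)
    total_var = target.var()
    if total_var == 0.0:
        raise ValueError("salience target has zero variance")
    fractions = np.empty(len(surprisal_by_layer))
    residual = target
    for k, layer_series in enumerate(surprisal_by_layer):
        x = np.asarray(layer_series, dtype=np.float64)
        if x.size != residual.size:
            raise ValueError("all series must share a common time base")
        residual = _regress_out(residual, x)
        fractions[k] = 1.0 - residual.var() / total_var
    return fractions


def random_baseline(salience: np.ndarray, surprisal_by_layer: list[np.ndarray],
                    keep_first: int = 1, seed: int = 0) -> np.ndarray:
    """Cumulative variance with layers after the first replaced by N(0, 1) noise."""
    rng = np.random.default_rng(seed)
    n = len(np.asarray(salience))
    series = [np.asarray(s, dtype=np.float64) for s in surprisal_by_layer]
    replaced = [s if k < keep_first else rng.standard_normal(n)
                for k, s in enumerate(series)]
    return cumulative_variance(salience, replaced)


@dataclass
class GroupContrast:
    difference: np.ndarray   # per-layer mean(a) - mean(b)
    layers: tuple[str, ...]
    t: float
    df: int
    p: float


def compare_groups(profiles_a: LayerMetricProfile,
                   profiles_b: LayerMetricProfile) -> GroupContrast:
    """Per-layer difference profile and an early-vs-deep t test on it."""
    if profiles_a.layers != profiles_b.layers:
        raise ValueError("layer sets must match")
    diff = profiles_a.mean() - profiles_b.mean()
    early = [diff[i] for i, l in enumerate(profiles_a.layers) if l in EARLY_LAYERS]
    deep = [diff[i] for i, l in enumerate(profiles_a.layers) if l in DEEP_LAYERS]
    early, deep = np.asarray(early), np.asarray(deep)
    df = early.size + deep.size - 2
    if early.std(ddof=1) == 0.0 and deep.std(ddof=1) == 0.0:
        t, p = (0.0, 1.0) if np.isclose(early.mean(), deep.mean()) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(early, deep)
    return GroupContrast(difference=diff, layers=profiles_a.layers,
                         t=float(t), df=df, p=float(p))


def event_window_stack(surprisal_values: np.ndarray, salience_values: np.ndarray,
                       event_indices: np.ndarray, delay_samples: int = 14,
                       half_window: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate +/- window segments around events for both signals.

    The salience window is shifted by the motor delay (in samples); events
    whose windows fall outside either series are dropped.  Returns
    (salience_stack, surprisal_stack) on a common concatenated time base —
    the inputs for event-restricted cumulative-variance analyses (e.g. per
    event category).
    """
    s_parts, b_parts = [], []
    for c in np.asarray(event_indices, dtype=int):
        cb = c + delay_samples
        if (c - half_window < 0 or c + half_window >= surprisal_values.size
                or cb - half_window < 0 or cb + half_window >= salience_values.size):
            continue
        s_parts.append(surprisal_values[c - half_window: c + half_window + 1])
        b_parts.append(salience_values[cb - half_window: cb + half_window + 1])
    if not s_parts:
        return np.array([]), np.array([])
    return np.concatenate(b_parts), np.concatenate(s_parts)
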