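"""Salient-event prediction from feature slopes and surprisal via LDA + ROC.

The scene is divided into overlapping time bins (2 s long, advanced by
0.5 s).  A bin is labeled 1 if a salient-event onset falls inside it.  Each
predictor — the slope of an acoustic feature (derivative smoothed by three
passes of an equally weighted moving average) or a layer's surprisal — is
averaged within each bin.  A linear discriminant classifier is trained and
scored under stratified five-fold cross-validation; pooled held-out scores
swept over thresholds give the ROC curve and its area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .behavior import SalientEvent
from .smoothing import smoothed_derivative


def feature_slope(track: np.ndarray, rate: float, window: int = 5,
                  passes: int = 3) -> np.ndarray:
    """Slope of a feature track: derivative then three moving-average passes.

    The 5-sample window at 10 Hz smooths out sub-half-second wiggles while
    keeping event-scale rises; it is exposed because the best setting
    depends on the event density of the material.
    """
    return smoothed_derivative(track, rate, window=window, passes=passes)


@dataclass
class BinTable:
    """Per-bin predictor means and event labels."""

    X: pd.DataFrame
    y: np.ndarray
    bin_starts_s: np.ndarray
    bin_s: float = 2.0
    step_s: float = 0.5
    n_skipped_events: int = 0

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def build_bins(features: dict[str, np.ndarray], events: list[SalientEvent],
               rate: float = 10.0, bin_s: float = 2.0, step_s: float = 0.5,
               t0_s: float = 0.0,
               alignment_s: dict[str, float] | None = None) -> BinTable:
    """Average each predictor in overlapping bins and label bins by events.

    A bin spanning [start, start + bin_s] is labeled 1 if any event onset
    lies inside it (closed interval).  ``alignment_s`` holds per-feature
    time shifts (positive = feature leads and is delayed to match salience)
    applied before binning.  Events outside the series span are skipped and
    counted.
    """
    lengths = {len(v) for v in features.values()}
    if len(lengths) != 1:
        raise ValueError("all predictor series must have equal length")
    n = lengths.pop()
    duration = n / rate
    alignment_s = alignment_s or {}
    starts = []
    k = 0
    while t0_s + k * step_s + bin_s <= t0_s + duration + 1e-9:
        starts.append(t0_s + k * step_s)
        k += 1
    starts = np.asarray(starts)
    cols = {}
    for name, track in features.items():
        x = np.asarray(track, dtype=np.float64)
        shift = int(round(alignment_s.get(name, 0.0) * rate))
        if shift > 0:
            x = np.concatenate([np.full(shift, x[0]), x[:-shift]])
        elif shift < 0:
            x = np.concatenate([x[-shift:], np.full(-shift, x[-1])])
        means = np.empty(starts.size)
        for i, s in enumerate(starts):
            a = int(round((s - t0_s) * rate))
            b = int(round((s - t0_s + bin_s) * rate))
            means[i] = x[a:b].mean()
        cols[name] = means
    y = np.zeros(starts.size, dtype=int)
    n_skipped = 0
    for ev in events:
        if ev.time_s < t0_s or ev.time_s > t0_s + duration:
            n_skipped += 1
            continue
        inside = (starts <= ev.time_s) & (ev.time_s <= starts + bin_s)
        y[inside] = 1
    return BinTable(X=pd.DataFrame(cols), y=y, bin_starts_s=starts,
                    bin_s=bin_s, step_s=step_s, n_skipped_events=n_skipped)


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    scores: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    labels: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def lda_classify(table: BinTable, columns: list[str] | None = None,
                 folds: int = 5, seed: int = 0) -> RocResult:
    """Cross-validated LDA scores pooled into one ROC curve.

    Fold assignment is seeded and stratified so both classes appear in
    every training fold; the discriminant assumes class-conditional
    Gaussians with a pooled covariance.
    """
    X = table.X[columns].to_numpy() if columns else table.X.to_numpy()
    y = table.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.bincount(y).min() < folds:
        raise ValueError("minority class smaller than the number of folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(y.size)
    for train, test in skf.split(X, y):
        clf = LinearDiscriminantAnalysis()  # svd solver tolerates collinearity
        clf.fit(X[train], y[train])
        scores[test] = clf.decision_function(X[test])
    fpr, tpr, thresholds = roc_curve(y, scores)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds,
                     auc=float(sk_auc(fpr, tpr)), scores=scores, labels=y.copy())


def compare_feature_sets(table: BinTable, acoustic_columns: list[str],
                         surprisal_columns: list[str], folds: int = 5,
                         seed: int = 0) -> tuple[RocResult, RocResult]:
    """ROC with acoustic slopes alone vs acoustic slopes + surprisal."""
    acoustic = lda_classify(table, columns=acoustic_columns, folds=folds, seed=seed)
    combined = lda_classify(table, columns=acoustic_columns + surprisal_columns,
                            folds=folds, seed=seed)
    return acoustic, combined
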