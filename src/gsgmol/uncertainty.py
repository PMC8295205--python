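"""MAE-histogram prediction intervals.

Given a reference set of absolute prediction errors (from molecules similar
to the ones to be predicted), the half-width epsilon is the error value
below which a target fraction (default 90%) of reference errors fall, read
off a cumulative histogram: equal-width bins over [0, max error] (20 by
default), cumulative mass evaluated at bin *upper edges*, epsilon = the
smallest upper edge whose cumulative mass reaches the level.  A point
prediction yhat then gets the interval [yhat - epsilon, yhat + epsilon].

The bin-edge rule quantizes the quantile upward by at most one bin width;
``method="quantile"`` gives the exact empirical quantile instead for
comparison and for calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PredictionInterval:
    """Symmetric interval half-width with its construction bookkeeping."""

    epsilon: float
    level: float = 0.90
    n_bins: int = 20
    source_n: int = 0
    method: str = "histogram"

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def contains(self, observed, predicted) -> np.ndarray:
        return np.abs(np.asarray(observed) - np.asarray(predicted)) <= self.epsilon


@dataclass(frozen=True)
class CoverageResult:
    percent: float
    n_inside: int
    n_total: int


def fit_interval(abs_errors, level: float = 0.90, n_bins: int = 20,
                 method: str = "histogram") -> PredictionInterval:
    """Fit the interval half-width from reference absolute errors.

    Parameters
    ----------
    abs_errors : array-like of nonnegative floats
        Reference |observed - predicted| values; at least ``n_bins`` of them.
    level : float in (0, 1), default 0.90
    n_bins : int, default 20
        Histogram bins over [0, max error].
    method : {"histogram", "quantile"}
        Cumulative-histogram edge rule, or the exact empirical quantile.
    """
    e = np.asarray(abs_errors, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("abs_errors must be non-empty")
    if np.any(e < 0):
        raise ValueError("absolute errors must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if method == "quantile":
        eps = float(np.quantile(e, level))
        return PredictionInterval(eps, level, n_bins, e.size, "quantile")
    if method != "histogram":
        raise ValueError(f"unknown method {method!r}")
    if e.size < n_bins:
        raise ValueError(
            f"need at least n_bins={n_bins} reference errors, got {e.size}"
        )
    top = float(e.max())
    if top == 0.0:
        return PredictionInterval(0.0, level, n_bins, e.size, "histogram")
    counts, edges = np.histogram(e, bins=n_bins, range=(0.0, top))
    cum = np.cumsum(counts) / e.size
    upper = edges[1:]
    hit = np.nonzero(cum >= level)[0]
    # cum reaches 1 at the last edge, so a hit always exists
    eps = float(upper[hit[0]])
    return PredictionInterval(eps, level, n_bins, e.size, "histogram")


def coverage(observed, predicted, interval: PredictionInterval) -> CoverageResult:
    """Fraction (as a percentage) of cases with |obs - pred| <= epsilon."""
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} vs {p.shape}")
    if o.size == 0:
        raise ValueError("need at least one observation")
    inside = int(np.sum(np.abs(o - p) <= interval.epsilon))
    return CoverageResult(percent=100.0 * inside / o.size,
                          n_inside=inside, n_total=o.size)
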