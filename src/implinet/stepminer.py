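"""One-step function fitting for adaptive per-feature thresholds.

Each feature's values are sorted and a step function with a single jump is
fitted by least squares: every split position partitions the sorted vector
into a low and a high segment, each approximated by its mean.  The split
minimizing the summed squared error defines the feature's discretization
threshold (midpoint of the two segment means).  Values within ``margin`` of
the threshold are labelled ``intermediate`` and excluded from quadrant counts
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LOW = "low"
HIGH = "high"
INTERMEDIATE = "intermediate"

#: relative SSE-reduction below which the best step is considered no step
DEGENERACY_RTOL = 1e-12


@dataclass(frozen=True)
class StepFit:
    """Best single-step fit of a sorted value vector.

    ``split_index`` is the number of samples in the low segment of the sorted
    vector; ``threshold`` is the midpoint of the two segment means.
    """

    split_index: int
    low_mean: float
    high_mean: float
    sse: float
    threshold: float
    degenerate: bool


def fit_step(values) -> StepFit:
    """Fit the least-squares one-step function over all split positions.

    The vector is sorted internally, so the fit is invariant to input order.
    Among splits tying on SSE the smallest split index is chosen.  The fit is
    degenerate when all values are equal or the best step reduces the SSE by
    less than ``DEGENERACY_RTOL`` relative to the zero-step (global mean) SSE.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("fit_step needs a 1-D vector with n >= 4")
    if not np.isfinite(x).all():
        raise ValueError("fit_step needs finite values")
    xs = np.sort(x)
    n = xs.size
    cs = np.cumsum(xs)
    css = np.cumsum(xs * xs)
    k = np.arange(1, n)  # low-segment sizes
    left = css[k - 1] - cs[k - 1] ** 2 / k
    rsum = cs[-1] - cs[k - 1]
    rss = css[-1] - css[k - 1]
    right = rss - rsum**2 / (n - k)
    sse = np.maximum(left, 0.0) + np.maximum(right, 0.0)
    total = max(css[-1] - cs[-1] ** 2 / n, 0.0)
    best = float(sse.min())
    tol = DEGENERACY_RTOL * max(total, 1.0)
    split = int(np.flatnonzero(sse <= best + tol)[0]) + 1
    degenerate = total <= 0.0 or (total - best) < DEGENERACY_RTOL * total
    low_mean = float(cs[split - 1] / split)
    high_mean = float((cs[-1] - cs[split - 1]) / (n - split))
    return StepFit(
        split_index=split,
        low_mean=low_mean,
        high_mean=high_mean,
        sse=float(sse[split - 1]),
        threshold=(low_mean + high_mean) / 2.0,
        degenerate=bool(degenerate),
    )


def discretize(values, fit: StepFit, margin: float = 0.5) -> np.ndarray:
    """Label values low/high/intermediate around the step threshold.

    ``low`` if x < threshold - margin, ``high`` if x > threshold + margin,
    ``intermediate`` otherwise.  Order matches the input (unsorted) order.
    A degenerate fit yields all-intermediate labels with a warning.
    """
    x = np.asarray(values, dtype=float)
    if fit.degenerate:
        log.warning("discretize called with degenerate fit; all intermediate")
        return np.full(x.shape, INTERMEDIATE, dtype=object)
    labels = np.full(x.shape, INTERMEDIATE, dtype=object)
    labels[x < fit.threshold - margin] = LOW
    labels[x > fit.threshold + margin] = HIGH
    return labels


def fit_table(matrix) -> pd.DataFrame:
    """Step fits for every feature of a FeatureMatrix, as an exportable table.

    Columns: feature_id, threshold, low_mean, high_mean, sse, degenerate.
    """
    rows = []
    for fid in matrix.feature_ids:
        f = fit_step(matrix.values[fid].to_numpy())
        rows.append(
            {
                "feature_id": fid,
                "threshold": f.threshold,
                "low_mean": f.low_mean,
                "high_mean": f.high_mean,
                "sse": f.sse,
                "degenerate": f.degenerate,
            }
        )
    return pd.DataFrame(rows)
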