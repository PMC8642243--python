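"""Otsu thresholding of marker expression and positivity calls.

The threshold is the histogram bin edge maximizing the between-class
variance ω0·ω1·(μ0−μ1)²; cells strictly above the threshold are called
marker-positive. Thresholds are computed per sample by default, since
background levels differ between samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, warn

__all__ = ["otsu_threshold", "fraction_positive", "per_sample_thresholds"]


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Between-class-variance-maximizing bin edge over n_bins equal-width bins.

    Candidate thresholds are the interior bin edges of an equal-width
    histogram over [min, max]. The class split puts values ≤ edge in class
    0 and values > edge in class 1; the returned edge maximizes
    ω0·ω1·(μ0−μ1)², ties broken by the smallest such edge.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values to threshold")
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise ValueError("degenerate distribution: all values identical")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")

    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    # Per-bin value mass uses bin centers (classic histogram formulation).
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]  # class 0 mass up to each interior edge
    w1 = total - w0
    m0 = np.cumsum(counts * centers)[:-1]
    m1 = (counts * centers).sum() - m0
    valid = (w0 > 0) & (w1 > 0)
    # an edge preceded by an empty bin yields the same partition as a smaller
    # edge; drop it so the smallest-edge tie-break is exact rather than left
    # to floating-point noise between mathematically equal variances
    canonical = np.ones_like(valid)
    canonical[1:] = counts[1:-1] > 0
    valid &= canonical
    between = np.zeros_like(m0)
    between[valid] = (
        w0[valid] * w1[valid]
        * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    )
    best = int(np.argmax(between))  # argmax returns the first (smallest) maximizer
    return float(edges[1:-1][best])


def fraction_positive(values: np.ndarray, threshold: float) -> float:
    """Fraction of values strictly greater than the threshold."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty vector")
    return float(np.count_nonzero(values > threshold) / values.size)


def per_sample_thresholds(
    expr: ExpressionMatrix,
    sample_id: np.ndarray | None = None,
    n_bins: int = 256,
    pooled: bool = False,
) -> pd.DataFrame:
    """Otsu thresholds per (sample, marker), or pooled across samples.

    Returns a tidy frame with columns sample_id, marker, threshold. Markers
    with a degenerate (constant) distribution in a sample are skipped with
    a warning.
    """
    if pooled or sample_id is None:
        sample_id = np.array(["pooled"] * expr.n_cells)
    sample_id = np.asarray(sample_id)
    rows = []
    for sample in pd.unique(sample_id):
        mask = sample_id == sample
        for j, marker in enumerate(expr.feature_names):
            col = expr.values[mask, j]
            try:
                t = otsu_threshold(col, n_bins=n_bins)
            except ValueError:
                warn(f"degenerate distribution for {marker!r} in sample {sample!r}; skipped")
                continue
            rows.append({"sample_id": sample, "marker": marker, "threshold": t})
    return pd.DataFrame(rows, columns=["sample_id", "marker", "threshold"])
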