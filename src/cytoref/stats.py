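"""Descriptive statistics for marker dynamics and gate homogeneity.

Covers the quantities summarized per marker and per gate: the mutual
information between pseudotime and expression (plug-in estimate on
equal-count bins, in nats), the log2 fold change between the start and
end of a trajectory, and the intragate dissimilarity (one minus the mean
pairwise Pearson correlation of within-gate expression profiles).
"""

from __future__ import annotations

import numpy as np

from .types import warn

__all__ = [
    "pseudotime_mutual_information",
    "trajectory_logfc",
    "intragate_dissimilarity",
]


def _quantile_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign equal-count (quantile) bin indices in [0, n_bins)."""
    edges = np.quantile(x, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, x, side="right")


def pseudotime_mutual_information(pt: np.ndarray, expr: np.ndarray, n_bins: int = 8) -> float:
    """Plug-in mutual information (nats) between pseudotime and expression.

    Both axes are discretized into ``n_bins`` equal-count bins; the MI of
    the joint histogram is computed with natural logarithms. Constant
    expression returns 0. The plug-in estimator is upward-biased at small
    n; a warning flags fewer than 5 cells per bin.
    """
    pt = np.asarray(pt, dtype=float).ravel()
    expr = np.asarray(expr, dtype=float).ravel()
    if pt.shape != expr.shape:
        raise ValueError("pt and expr must have equal length")
    if pt.size == 0:
        raise ValueError("empty input")
    if np.all(expr == expr[0]):
        return 0.0
    if pt.size < n_bins * 5:
        warn(f"only {pt.size} cells for {n_bins} bins; MI estimate is unstable")
    bx = _quantile_bin(pt, n_bins)
    by = _quantile_bin(expr, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def trajectory_logfc(
    pt: np.ndarray,
    expr: np.ndarray,
    edge_fraction: float = 0.1,
    pseudocount: float = 1.0,
) -> float:
    """log2 fold change of mean expression between trajectory end and start.

    The start window is cells with pseudotime ≤ the ``edge_fraction``
    quantile, the end window cells ≥ the 1−``edge_fraction`` quantile;
    the ratio of window means is stabilized with a pseudocount on the
    normalized scale.
    """
    if not 0.0 < edge_fraction < 0.5:
        raise ValueError("edge_fraction must lie in (0, 0.5)")
    pt = np.asarray(pt, dtype=float).ravel()
    expr = np.asarray(expr, dtype=float).ravel()
    if pt.shape != expr.shape:
        raise ValueError("pt and expr must have equal length")
    lo = np.quantile(pt, edge_fraction)
    hi = np.quantile(pt, 1.0 - edge_fraction)
    start = expr[pt <= lo]
    end = expr[pt >= hi]
    if start.size < 2 or end.size < 2:
        raise ValueError("need at least 2 cells in each edge window")
    return float(np.log2((end.mean() + pseudocount) / (start.mean() + pseudocount)))


def intragate_dissimilarity(expr_subset: np.ndarray) -> float:
    """One minus the mean pairwise Pearson correlation of cell profiles.

    Rows are cells inside the gate, columns the concatenated normalized
    gene and surface-antigen features. Cells with a constant profile have
    undefined correlations; their pairs are excluded with a warning.
    """
    x = np.asarray(expr_subset, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a cells × features matrix with ≥ 2 cells and ≥ 2 features")
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warn(f"{int(constant.sum())} cell(s) with constant profiles excluded")
        x = x[~constant]
    m = x.shape[0]
    if m < 2:
        raise ValueError("fewer than 2 cells with non-constant profiles")
    corr = np.corrcoef(x)
    iu = np.triu_indices(m, k=1)
    return float(1.0 - corr[iu].mean())
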