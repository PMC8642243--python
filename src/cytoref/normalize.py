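"""Count normalization for antibody-derived tags and gene UMIs.

Antibody counts are centered per cell with a log-ratio (CLR) transform,
ln(x+1) minus the cell's mean ln(x+1), which absorbs unspecific binding
background. Gene counts are depth-normalized to a fixed total and
log1p-transformed.
"""

from __future__ import annotations

import numpy as np

from .types import ExpressionMatrix, warn

__all__ = ["clr_normalize", "log_normalize"]


def clr_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Centered log-ratio normalization across features within each cell.

    out[c, f] = ln(x[c, f] + 1) − mean_f ln(x[c, ·] + 1), so each output
    row has mean exactly 0. A cell with all-zero counts maps to an all-zero
    row (with a warning), not an error.
    """
    if counts.layer != "raw_counts":
        raise ValueError("clr_normalize expects the raw_counts layer")
    logged = np.log1p(counts.values)
    out = logged - logged.mean(axis=1, keepdims=True)
    zero_rows = ~counts.values.any(axis=1)
    if zero_rows.any():
        warn(f"{int(zero_rows.sum())} cell(s) with all-zero counts map to zero rows")
    return ExpressionMatrix(
        values=out,
        feature_names=list(counts.feature_names),
        cell_ids=list(counts.cell_ids),
        feature_kind=list(counts.feature_kind),
        layer="normalized",
    )


def log_normalize(counts: ExpressionMatrix, scale_total: float = 10_000.0) -> ExpressionMatrix:
    """Depth normalization: out[c, f] = ln(1 + scale_total · x[c, f] / total[c]).

    Cells with zero total map to all-zero rows with a warning.
    """
    if counts.layer != "raw_counts":
        raise ValueError("log_normalize expects the raw_counts layer")
    if scale_total <= 0:
        raise ValueError("scale_total must be positive")
    totals = counts.values.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        warn(f"{int(zero.sum())} cell(s) with zero total counts map to zero rows")
    safe = np.where(totals == 0, 1.0, totals)
    out = np.log1p(scale_total * counts.values / safe)
    out[zero] = 0.0
    return ExpressionMatrix(
        values=out,
        feature_names=list(counts.feature_names),
        cell_ids=list(counts.cell_ids),
        feature_kind=list(counts.feature_kind),
        layer="normalized",
    )
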