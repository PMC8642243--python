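"""Core data containers shared across the toolkit.

The containers are deliberately thin: a validated matrix plus aligned
metadata, built on numpy/pandas. Validation happens at construction so
that downstream algorithms can assume the invariants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ReferenceAtlas",
    "QueryCytometry",
    "MarkerStats",
    "GateMetrics",
    "AbundanceData",
    "ProjectionResult",
]

FeatureKind = Literal["antibody", "gene"]
Layer = Literal["raw_counts", "normalized"]


def _check_unique(names: Sequence[str], what: str) -> None:
    seen = pd.Index(names)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """A cells × features expression matrix with aligned metadata.

    Parameters
    ----------
    values
        2-D array, cells in rows and features in columns.
    feature_names
        Unique feature (marker/gene) names, one per column.
    cell_ids
        Unique cell identifiers, one per row.
    feature_kind
        Per-feature tag, ``"antibody"`` or ``"gene"``. A single string is
        broadcast to all features.
    layer
        ``"raw_counts"`` (non-negative integers) or ``"normalized"``
        (finite reals).
    """

    values: np.ndarray
    feature_names: list[str]
    cell_ids: list[str]
    feature_kind: list[str] = field(default=None)  # type: ignore[assignment]
    layer: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells × features matrix")
        self.feature_names = [str(f) for f in self.feature_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if isinstance(self.feature_kind, str) or self.feature_kind is None:
            kind = self.feature_kind or "antibody"
            self.feature_kind = [kind] * len(self.feature_names)
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length does not match matrix columns")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length does not match matrix rows")
        if len(self.feature_kind) != len(self.feature_names):
            raise ValueError("feature_kind length does not match features")
        bad = set(self.feature_kind) - {"antibody", "gene"}
        if bad:
            raise ValueError(f"unknown feature_kind values: {sorted(bad)}")
        _check_unique(self.feature_names, "feature names")
        _check_unique(self.cell_ids, "cell ids")
        if self.layer not in ("raw_counts", "normalized"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer == "raw_counts":
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValueError("raw_counts layer must hold non-negative integers")
        else:
            if not np.all(np.isfinite(self.values)):
                raise ValueError("normalized layer must hold finite reals")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not in matrix") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_index(name)]

    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            cell_ids=[self.cell_ids[i] for i in np.atleast_1d(idx)],
            feature_kind=list(self.feature_kind),
            layer=self.layer,
        )

    def subset_features(self, names: Sequence[str]) -> "ExpressionMatrix":
        cols = [self.feature_index(n) for n in names]
        return ExpressionMatrix(
            values=self.values[:, cols],
            feature_names=[self.feature_names[i] for i in cols],
            cell_ids=list(self.cell_ids),
            feature_kind=[self.feature_kind[i] for i in cols],
            layer=self.layer,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.feature_names)


@dataclass
class ReferenceAtlas:
    """A normalized reference expression matrix plus per-cell annotation.

    ``latent`` holds the low-dimensional factor coordinates used for
    mapping-consistency scoring, ``embedding`` a 2-D display layout, and
    ``pseudotime`` one column per differentiation trajectory with NaN for
    cells not on that trajectory.
    """

    expr: ExpressionMatrix
    cell_type: np.ndarray
    sample_id: np.ndarray
    latent: np.ndarray
    embedding: np.ndarray
    pseudotime: pd.DataFrame

    def __post_init__(self) -> None:
        n = self.expr.n_cells
        self.cell_type = np.asarray(self.cell_type)
        self.sample_id = np.asarray(self.sample_id)
        self.latent = np.asarray(self.latent, dtype=float)
        self.embedding = np.asarray(self.embedding, dtype=float)
        if self.expr.layer != "normalized":
            raise ValueError("atlas expression must be on the normalized layer")
        if len(self.cell_type) != n or len(self.sample_id) != n:
            raise ValueError("per-cell annotation length mismatch")
        if self.latent.ndim != 2 or self.latent.shape[0] != n:
            raise ValueError("latent must be cells × D")
        if self.embedding.shape != (n, 2):
            raise ValueError("embedding must have exactly 2 columns")
        if not isinstance(self.pseudotime, pd.DataFrame):
            self.pseudotime = pd.DataFrame(self.pseudotime)
        if len(self.pseudotime) != n:
            raise ValueError("pseudotime rows must match cells")
        pt = self.pseudotime.to_numpy(dtype=float)
        defined = pt[np.isfinite(pt)]
        if defined.size and (defined.min() < 0 or defined.max() > 1):
            raise ValueError("defined pseudotime values must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.expr.n_cells

    @property
    def trajectories(self) -> list[str]:
        return [str(c) for c in self.pseudotime.columns]

    def subset_cells(self, idx: np.ndarray) -> "ReferenceAtlas":
        idx = np.asarray(idx)
        return ReferenceAtlas(
            expr=self.expr.subset_cells(idx),
            cell_type=self.cell_type[idx],
            sample_id=self.sample_id[idx],
            latent=self.latent[idx],
            embedding=self.embedding[idx],
            pseudotime=self.pseudotime.iloc[idx].reset_index(drop=True),
        )


@dataclass
class QueryCytometry:
    """Events × markers matrix of transformed fluorescence intensities.

    Display/variance-stabilising transforms (logicle, arcsinh) are assumed
    applied upstream; rank-based projection is invariant to any strictly
    increasing per-marker transform.
    """

    intensities: np.ndarray
    marker_names: list[str]
    event_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be events × markers")
        self.marker_names = [str(m) for m in self.marker_names]
        _check_unique(self.marker_names, "marker names")
        if len(self.marker_names) != self.intensities.shape[1]:
            raise ValueError("marker_names length does not match columns")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.event_ids is None:
            self.event_ids = [f"event{i}" for i in range(self.intensities.shape[0])]
        elif len(self.event_ids) != self.intensities.shape[0]:
            raise ValueError("event_ids length does not match rows")

    @property
    def n_events(self) -> int:
        return self.intensities.shape[0]


@dataclass
class MarkerStats:
    """Summary statistics for one surface marker."""

    marker: str
    mean_expression: float
    fraction_positive: float
    mutual_information: dict[str, float] = field(default_factory=dict)
    start_end_logfc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_positive <= 1.0:
            raise ValueError("fraction_positive must lie in [0, 1]")
        for traj, mi in self.mutual_information.items():
            if mi < 0:
                raise ValueError(f"mutual information for {traj!r} is negative")


@dataclass
class GateMetrics:
    """Purity (precision) and recall bookkeeping for one gate.

    purity = TP / (TP + FP): the proportion of target cells in the final
    gate. recall = TP / (TP + FN): the proportion of target cells captured
    from their original total population. An empty gate has undefined
    purity, reported as 0 with ``empty_gate=True``.
    """

    tp: int
    fp: int
    fn: int
    empty_gate: bool = False

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        self.empty_gate = (self.tp + self.fp) == 0

    @property
    def gate_size(self) -> int:
        return self.tp + self.fp

    @property
    def target_size(self) -> int:
        return self.tp + self.fn

    @property
    def purity(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else 0.0


@dataclass
class AbundanceData:
    """Per-individual target/total counts with group labels.

    ``k[i]`` target-cell count, ``n[i]`` gate-total count, ``group[i]``
    the experimental group (e.g. young vs aged).
    """

    k: np.ndarray
    n: np.ndarray
    group: np.ndarray
    individual_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        self.group = np.asarray(self.group)
        if not (len(self.k) == len(self.n) == len(self.group)):
            raise ValueError("k, n, group must have equal length")
        if np.any(self.n <= 0):
            raise ValueError("gate totals n must be positive")
        if np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("require 0 <= k <= n")
        if self.individual_id is None:
            self.individual_id = np.array([f"ind{i}" for i in range(len(self.k))])

    @property
    def n_individuals(self) -> int:
        return len(self.k)


@dataclass
class ProjectionResult:
    """Per-event projection output (one table for the whole query)."""

    neighbor_ids: np.ndarray  # events × k, atlas cell ids
    cosine_distances: np.ndarray  # events × k
    transferred_label: np.ndarray
    embedding_coords: np.ndarray  # events × 2
    pseudotime: pd.DataFrame  # events × trajectories, NaN if undefined
    inconsistency: np.ndarray
    kept: np.ndarray
    event_ids: list[str]
    inconsistency_threshold: float

    def __post_init__(self) -> None:
        n = len(self.event_ids)
        for name in ("neighbor_ids", "cosine_distances", "transferred_label",
                     "embedding_coords", "inconsistency", "kept"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match events")
        if np.any(self.inconsistency < 0):
            raise ValueError("inconsistency must be non-negative")
        expected = self.inconsistency <= self.inconsistency_threshold
        if not np.array_equal(np.asarray(self.kept, dtype=bool), expected):
            raise ValueError("kept flag inconsistent with threshold")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "event_id": self.event_ids,
                "label": self.transferred_label,
                "embedding_x": self.embedding_coords[:, 0],
                "embedding_y": self.embedding_coords[:, 1],
                "inconsistency": self.inconsistency,
                "kept": np.asarray(self.kept, dtype=bool),
            }
        )
        for traj in self.pseudotime.columns:
            df[f"pseudotime_{traj}"] = self.pseudotime[traj].to_numpy()
        return df


def warn(message: str) -> None:
    """Emit a toolkit warning (single choke point for tests)."""
    warnings.warn(message, UserWarning, stacklevel=3)
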