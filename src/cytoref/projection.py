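"""Nearest rank neighbors (NRN): project cytometry events onto a reference atlas.

Cytometry intensities and antibody-tag counts live on incomparable
scales, but their per-marker rank orderings are comparable. NRN maps
every shared marker to [0, 1] by ranks, separately within the reference
and within the query, finds each event's k nearest reference cells by
cosine distance in that rank space, and transfers label, 2-D embedding
position and pseudotime from the neighbors. A consistency score — the
mean pairwise Euclidean distance of the neighbors in the reference's
latent (factor) space — flags events whose neighbors are scattered
across unrelated states; events above a user threshold are dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .types import ProjectionResult, QueryCytometry, ReferenceAtlas, warn

__all__ = [
    "rank_normalize",
    "cosine_distance",
    "inconsistency_score",
    "project",
    "shared_markers",
]


def rank_normalize(values: np.ndarray) -> np.ndarray:
    """Map values to [0, 1] by average ranks: (rank − 1) / (n − 1).

    The minimum maps to exactly 0 and the maximum to exactly 1; ties get
    the mean of the ranks they span. Invariant under any strictly
    increasing transform of the input.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values to rank-normalize")
    if np.all(values == values[0]):
        warn("all values tied; rank-normalized to 0.5")
        return np.full(n, 0.5)
    return (rankdata(values, method="average") - 1.0) / (n - 1.0)


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 − cos(a, b); errors on zero-norm input (undefined direction)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size == 0:
        raise ValueError("vectors must have equal positive length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("undefined direction: zero-norm vector")
    return float(1.0 - (a @ b) / (na * nb))


def inconsistency_score(neighbor_latent: np.ndarray, mode: str = "pairwise") -> float:
    """Mapping-consistency score of a neighbor set in latent space.

    ``pairwise`` (default): mean Euclidean distance over all unordered
    neighbor pairs. ``centroid``: mean distance of neighbors to their
    centroid.
    """
    x = np.asarray(neighbor_latent, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 neighbors")
    if mode == "pairwise":
        return float(pdist(x).mean())
    if mode == "centroid":
        return float(np.linalg.norm(x - x.mean(axis=0), axis=1).mean())
    raise ValueError(f"unknown mode {mode!r}")


def shared_markers(query: QueryCytometry, atlas: ReferenceAtlas) -> list[str]:
    """Antibody markers present in both query and atlas, in atlas order."""
    qset = set(query.marker_names)
    return [
        f
        for f, kind in zip(atlas.expr.feature_names, atlas.expr.feature_kind)
        if kind == "antibody" and f in qset
    ]


def _rank_matrix(values: np.ndarray) -> np.ndarray:
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        if np.all(col == col[0]):
            out[:, j] = 0.5
        else:
            out[:, j] = (rankdata(col, method="average") - 1.0) / (len(col) - 1.0)
    return out


def project(
    query: QueryCytometry,
    atlas: ReferenceAtlas,
    k: int = 4,
    inconsistency_threshold: float = 8.0,
    inconsistency_mode: str = "pairwise",
    auto_threshold_quantile: float | None = None,
) -> ProjectionResult:
    """Project query events into the atlas via rank-space cosine kNN.

    For each event: restrict both datasets to shared markers, rank-
    normalize each marker within each dataset, take the k reference cells
    with smallest cosine distance (ties broken by atlas cell order),
    transfer the neighbors' majority label (nearest neighbor breaks
    ties), average their embedding rows and their defined pseudotime
    values, and score consistency in latent space. Events with score
    above the threshold are flagged as not kept.

    ``auto_threshold_quantile``, if given, overrides the fixed threshold
    with the corresponding quantile of the observed scores (e.g. 0.95
    drops the top 5% least consistent events) — the fixed default of 8 is
    only meaningful on a particular latent scaling.
    """
    markers = shared_markers(query, atlas)
    if len(markers) < 2:
        raise ValueError("need at least 2 shared markers between query and atlas")
    if not 1 <= k <= atlas.n_cells:
        raise ValueError("k must lie in [1, number of atlas cells]")

    ref = _rank_matrix(atlas.expr.subset_features(markers).values)
    qry = _rank_matrix(query.intensities[:, [query.marker_names.index(m) for m in markers]])

    # Cosine distance via normalized rows; rank rows are nonzero unless every
    # marker is tied at its minimum for that cell — guard with an epsilon-free check.
    def _unit(x: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("undefined direction: event/cell with zero rank profile")
        return x / norms

    dist = 1.0 - _unit(qry) @ _unit(ref).T  # events × cells
    # Stable argsort => distance ties broken by atlas cell index order.
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]

    n_events = query.n_events
    neighbor_ids = np.array(
        [[atlas.expr.cell_ids[j] for j in order[i]] for i in range(n_events)], dtype=object
    )
    nn_dist = np.take_along_axis(dist, order, axis=1)

    labels = np.empty(n_events, dtype=object)
    for i in range(n_events):
        neigh_labels = atlas.cell_type[order[i]]
        uniq, counts = np.unique(neigh_labels, return_counts=True)
        winners = uniq[counts == counts.max()]
        if len(winners) == 1:
            labels[i] = winners[0]
        else:
            labels[i] = neigh_labels[0]  # nearest neighbor breaks the tie

    embedding = atlas.embedding[order].mean(axis=1)

    pt_ref = atlas.pseudotime.to_numpy(dtype=float)  # cells × trajectories
    pt_neigh = pt_ref[order]  # events × k × trajectories
    defined = ~np.isnan(pt_neigh)
    n_def = defined.sum(axis=1)
    sums = np.where(defined, pt_neigh, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pt_mean = np.where(n_def > 0, sums / np.maximum(n_def, 1), np.nan)
    pt = pd.DataFrame(pt_mean, columns=atlas.pseudotime.columns)

    if k >= 2:
        inconsistency = np.array(
            [inconsistency_score(atlas.latent[order[i]], mode=inconsistency_mode)
             for i in range(n_events)]
        )
    else:
        inconsistency = np.zeros(n_events)

    threshold = inconsistency_threshold
    if auto_threshold_quantile is not None:
        threshold = float(np.quantile(inconsistency, auto_threshold_quantile))
    kept = inconsistency <= threshold

    return ProjectionResult(
        neighbor_ids=neighbor_ids,
        cosine_distances=nn_dist,
        transferred_label=labels,
        embedding_coords=embedding,
        pseudotime=pt,
        inconsistency=inconsistency,
        kept=kept,
        event_ids=list(query.event_ids),
        inconsistency_threshold=threshold,
    )
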