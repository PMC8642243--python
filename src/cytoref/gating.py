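"""Data-driven design and evaluation of cytometry gating schemes.

Three families of schemes are supported:

* decision trees (CART) over continuous marker expression or over
  Otsu-binarized marker indicators, pruned to a surface-marker budget;
* hypergate-style axis-aligned hyperrectangles fit by coordinate ascent
  on the F_beta trade-off of purity and recall, with per-channel
  contributions used to respect a marker budget;
* expert schemes: ordered marker-positivity predicates resolved by Otsu
  thresholds recomputed on the retained events at each step, mirroring
  manual sequential gating.

Every scheme is scored by purity (precision within the gate) and recall
(fraction of the target population captured).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .thresholds import otsu_threshold
from .types import ExpressionMatrix, GateMetrics, warn

__all__ = [
    "TreeSplit",
    "TreeLeaf",
    "Bound",
    "GatingScheme",
    "HypergateResult",
    "evaluate_gate",
    "fit_tree",
    "fit_hypergate",
    "balanced_subsample",
    "split_by_cd34",
    "evaluate_expert_scheme",
]


# ---------------------------------------------------------------------------
# Scheme representation


@dataclass
class TreeLeaf:
    label: str


@dataclass
class TreeSplit:
    """Binary split: events with marker value ≤ threshold go left, > right."""

    marker: str
    threshold: float
    left: Union["TreeSplit", TreeLeaf]
    right: Union["TreeSplit", TreeLeaf]


@dataclass
class Bound:
    marker: str
    bound_type: str  # "min" or "max"
    value: float

    def __post_init__(self) -> None:
        if self.bound_type not in ("min", "max"):
            raise ValueError(f"bound_type must be 'min' or 'max', got {self.bound_type!r}")
        if not np.isfinite(self.value):
            raise ValueError("bound value must be finite")


@dataclass
class GatingScheme:
    """A serializable gating scheme of one of three kinds.

    ``tree``: a root TreeSplit/TreeLeaf whose leaves carry population
    labels. ``hyperrectangle``: conjunction of min/max bounds (min is
    inclusive ≥, max inclusive ≤) selecting ``target_population``.
    ``expert``: ordered (marker, sign) predicates resolved by Otsu at
    evaluation time.
    """

    kind: str
    tree: Optional[Union[TreeSplit, TreeLeaf]] = None
    bounds: list[Bound] = field(default_factory=list)
    predicates: list[tuple[str, str]] = field(default_factory=list)
    target_population: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("tree", "hyperrectangle", "expert"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "tree" and self.tree is None:
            raise ValueError("tree scheme requires a tree")
        if self.kind == "expert":
            for marker, sign in self.predicates:
                if sign not in ("+", "-"):
                    raise ValueError(f"expert sign must be '+' or '-', got {sign!r}")

    def markers_used(self) -> list[str]:
        """Distinct markers referenced by the scheme, in first-use order."""
        seen: list[str] = []

        def add(m: str) -> None:
            if m not in seen:
                seen.append(m)

        if self.kind == "tree":
            def walk(node):
                if isinstance(node, TreeSplit):
                    add(node.marker)
                    walk(node.left)
                    walk(node.right)
            walk(self.tree)
        elif self.kind == "hyperrectangle":
            for b in self.bounds:
                add(b.marker)
        else:
            for marker, _ in self.predicates:
                add(marker)
        return seen


@dataclass
class HypergateResult:
    scheme: GatingScheme
    contributions: dict[str, float]
    f_beta: float
    history: list[float]  # accepted F_beta values, in acceptance order

    def __iter__(self):  # allow (scheme, contributions) unpacking
        return iter((self.scheme, self.contributions))


# ---------------------------------------------------------------------------
# Evaluation


def _as_values(expr: Union[ExpressionMatrix, np.ndarray], markers: Sequence[str] = ()) -> np.ndarray:
    if isinstance(expr, ExpressionMatrix):
        return expr.values
    return np.asarray(expr, dtype=float)


def _marker_column(expr: Union[ExpressionMatrix, np.ndarray], marker: str,
                   marker_names: Optional[Sequence[str]] = None) -> np.ndarray:
    if isinstance(expr, ExpressionMatrix):
        return expr.column(marker)
    if marker_names is None:
        raise ValueError("marker_names required for a bare array")
    names = list(marker_names)
    if marker not in names:
        raise KeyError(f"marker {marker!r} not in expression data")
    return np.asarray(expr, dtype=float)[:, names.index(marker)]


def _target_mask(truth: np.ndarray, target_population: Optional[str]) -> np.ndarray:
    truth = np.asarray(truth)
    if truth.dtype == bool:
        return truth
    if target_population is None:
        raise ValueError("label-vector truth requires a target_population")
    return truth == target_population


def _metrics(gate: np.ndarray, target: np.ndarray) -> GateMetrics:
    gate = np.asarray(gate, dtype=bool)
    target = np.asarray(target, dtype=bool)
    tp = int(np.count_nonzero(gate & target))
    fp = int(np.count_nonzero(gate & ~target))
    fn = int(np.count_nonzero(~gate & target))
    m = GateMetrics(tp=tp, fp=fp, fn=fn)
    if m.empty_gate:
        warn("empty gate: purity undefined, reported as 0")
    return m


def hyperrectangle_mask(bounds: Sequence[Bound], expr, marker_names=None) -> np.ndarray:
    n = (expr.n_cells if isinstance(expr, ExpressionMatrix)
         else np.asarray(expr).shape[0])
    mask = np.ones(n, dtype=bool)
    for b in bounds:
        col = _marker_column(expr, b.marker, marker_names)
        mask &= (col >= b.value) if b.bound_type == "min" else (col <= b.value)
    return mask


def _route_tree(node, expr, marker_names=None) -> dict[int, tuple[str, np.ndarray]]:
    """Route all events through the tree; returns {leaf_id: (label, mask)}."""
    n = (expr.n_cells if isinstance(expr, ExpressionMatrix)
         else np.asarray(expr).shape[0])
    leaves: dict[int, tuple[str, np.ndarray]] = {}
    counter = [0]

    def walk(node, mask):
        if isinstance(node, TreeLeaf):
            leaves[counter[0]] = (node.label, mask)
            counter[0] += 1
            return
        col = _marker_column(expr, node.marker, marker_names)
        walk(node.left, mask & (col <= node.threshold))
        walk(node.right, mask & (col > node.threshold))

    walk(node, np.ones(n, dtype=bool))
    return leaves


def evaluate_gate(
    scheme: GatingScheme,
    expr: Union[ExpressionMatrix, np.ndarray],
    truth: np.ndarray,
    marker_names: Optional[Sequence[str]] = None,
    otsu_bins: int = 256,
):
    """Score a gating scheme against ground-truth labels.

    For tree schemes, returns a list of per-leaf dicts with the leaf's
    label and GateMetrics (target = the leaf's label). For
    hyperrectangle and expert schemes, returns a single GateMetrics
    against the scheme's target population (``truth`` may be a boolean
    mask or a label vector).
    """
    if scheme.kind == "tree":
        truth = np.asarray(truth)
        leaves = _route_tree(scheme.tree, expr, marker_names)
        out = []
        for leaf_id, (label, mask) in leaves.items():
            m = _metrics(mask, truth == label)
            out.append({"leaf": leaf_id, "label": label, "metrics": m})
        return out
    if scheme.kind == "hyperrectangle":
        gate = hyperrectangle_mask(scheme.bounds, expr, marker_names)
        return _metrics(gate, _target_mask(truth, scheme.target_population))
    return evaluate_expert_scheme(
        scheme.predicates, expr, _target_mask(truth, scheme.target_population),
        marker_names=marker_names, n_bins=otsu_bins,
    )


# ---------------------------------------------------------------------------
# Decision trees


def _sklearn_to_scheme(clf: DecisionTreeClassifier, marker_names: Sequence[str],
                       thresholds: Optional[dict[str, float]] = None) -> Union[TreeSplit, TreeLeaf]:
    """Convert a fitted sklearn tree to the scheme representation.

    ``thresholds`` maps marker → continuous threshold for trees fit on
    binarized indicators (the 0/1 split at 0.5 is replaced by the Otsu
    threshold so the scheme applies to continuous data).
    """
    t = clf.tree_
    classes = clf.classes_

    def build(i: int):
        if t.children_left[i] == -1:
            label = classes[int(np.argmax(t.value[i]))]
            return TreeLeaf(label=str(label))
        marker = str(marker_names[t.feature[i]])
        thr = float(t.threshold[i])
        if thresholds is not None:
            thr = thresholds[marker]
        return TreeSplit(
            marker=marker,
            threshold=thr,
            left=build(t.children_left[i]),
            right=build(t.children_right[i]),
        )

    return build(0)


def fit_tree(
    expr: Union[ExpressionMatrix, np.ndarray],
    labels: np.ndarray,
    max_markers: int = 12,
    binarize: bool = False,
    min_leaf: int = 20,
    marker_names: Optional[Sequence[str]] = None,
    otsu_bins: int = 256,
    random_state: int = 0,
) -> GatingScheme:
    """Fit a CART gating tree, pruned to a surface-marker budget.

    Gini impurity, binary axis-aligned splits, greedy growth with
    ``min_leaf`` events per leaf, then cost-complexity pruning with the
    penalty raised until at most ``max_markers`` distinct markers remain.
    With ``binarize=True``, markers are first binarized at their Otsu
    thresholds and splits are placed at those thresholds.
    """
    if isinstance(expr, ExpressionMatrix):
        marker_names = expr.feature_names
        x = expr.values
    else:
        x = np.asarray(expr, dtype=float)
        if marker_names is None:
            marker_names = [f"m{j}" for j in range(x.shape[1])]
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        warn("fewer than 2 classes; returning a single-leaf scheme")
        return GatingScheme(kind="tree", tree=TreeLeaf(label=str(labels[0])))

    otsu_map: Optional[dict[str, float]] = None
    if binarize:
        otsu_map = {}
        xb = np.empty_like(x)
        for j, m in enumerate(marker_names):
            t = otsu_threshold(x[:, j], n_bins=otsu_bins)
            otsu_map[str(m)] = t
            xb[:, j] = (x[:, j] > t).astype(float)
        x_fit = xb
    else:
        x_fit = x

    def fit_at(alpha: float) -> DecisionTreeClassifier:
        clf = DecisionTreeClassifier(
            criterion="gini",
            min_samples_leaf=min_leaf,
            ccp_alpha=alpha,
            random_state=random_state,
        )
        clf.fit(x_fit, labels)
        return clf

    clf = fit_at(0.0)

    def n_markers(c: DecisionTreeClassifier) -> int:
        t = c.tree_
        used = {t.feature[i] for i in range(t.node_count) if t.children_left[i] != -1}
        return len(used)

    if n_markers(clf) > max_markers:
        path = clf.cost_complexity_pruning_path(x_fit, labels)
        for alpha in np.unique(path.ccp_alphas):
            clf = fit_at(float(alpha) + 1e-12)
            if n_markers(clf) <= max_markers:
                break
        if n_markers(clf) > max_markers:  # pragma: no cover - full pruning always reaches 0
            clf = fit_at(np.inf)

    if clf.tree_.node_count == 1:
        warn("degenerate input: tree collapsed to a single leaf")

    root = _sklearn_to_scheme(clf, marker_names, thresholds=otsu_map)
    return GatingScheme(kind="tree", tree=root)


# ---------------------------------------------------------------------------
# Hypergate-style hyperrectangles


def _f_beta(tp: np.ndarray, fp: np.ndarray, n_target: int, beta: float) -> np.ndarray:
    """F_beta of purity and recall; 0 where the gate is empty."""
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    gate = tp + fp
    with np.errstate(divide="ignore", invalid="ignore"):
        purity = np.where(gate > 0, tp / np.where(gate > 0, gate, 1), 0.0)
        recall = tp / n_target
        denom = beta**2 * purity + recall
        f = np.where(denom > 0, (1 + beta**2) * purity * recall / np.where(denom > 0, denom, 1), 0.0)
    return f


def fit_hypergate(
    expr: Union[ExpressionMatrix, np.ndarray],
    target_mask: np.ndarray,
    max_markers: Optional[int] = None,
    beta: float = 1.0,
    marker_names: Optional[Sequence[str]] = None,
    tol: float = 1e-12,
    max_sweeps: int = 200,
) -> HypergateResult:
    """Fit an axis-aligned hyperrectangle maximizing F_beta(purity, recall).

    Coordinate ascent: sweep over channels; for each channel and side
    (min, then max) evaluate every candidate bound at an observed value
    (plus "no bound") given the other bounds, and accept the best
    strictly improving candidate. Converges when a full sweep accepts
    nothing. The channel contribution of a marker is the F_beta drop when
    its bounds are removed (without re-optimization); when
    ``max_markers`` is given, only the top contributing channels are
    retained and the ascent is re-run on that subset.
    """
    if isinstance(expr, ExpressionMatrix):
        marker_names = expr.feature_names
        x = expr.values
    else:
        x = np.asarray(expr, dtype=float)
        if marker_names is None:
            marker_names = [f"m{j}" for j in range(x.shape[1])]
    marker_names = [str(m) for m in marker_names]
    target = np.asarray(target_mask, dtype=bool)
    if target.shape[0] != x.shape[0]:
        raise ValueError("target_mask length must match events")
    n_target = int(target.sum())
    if n_target == 0 or n_target == len(target):
        raise ValueError("target_mask needs at least 1 positive and 1 negative event")

    n, p = x.shape

    def ascend(channels: list[int], mins: np.ndarray, maxs: np.ndarray,
               history: list[float]) -> tuple[np.ndarray, np.ndarray, float]:
        def gate_mask(exclude: Optional[int] = None) -> np.ndarray:
            mask = np.ones(n, dtype=bool)
            for j in channels:
                if j == exclude:
                    continue
                mask &= (x[:, j] >= mins[j]) & (x[:, j] <= maxs[j])
            return mask

        def current_f() -> float:
            g = gate_mask()
            return float(_f_beta(np.array(np.count_nonzero(g & target)),
                                 np.array(np.count_nonzero(g & ~target)),
                                 n_target, beta))

        f_cur = current_f()
        for _ in range(max_sweeps):
            improved = False
            for j in channels:
                others = gate_mask(exclude=j)
                col = x[:, j]
                for side in ("min", "max"):
                    # events passing every other bound and this channel's
                    # opposite-side bound
                    if side == "min":
                        base = others & (col <= maxs[j])
                    else:
                        base = others & (col >= mins[j])
                    vals = col[base]
                    tgt = target[base]
                    if vals.size == 0:
                        continue
                    order = np.argsort(vals, kind="stable")
                    v_sorted = vals[order]
                    t_sorted = tgt[order].astype(float)
                    # candidate thresholds: unbounded, then each distinct
                    # observed value (inclusive bound at that value)
                    distinct = np.ones(v_sorted.size, dtype=bool)
                    distinct[1:] = v_sorted[1:] != v_sorted[:-1]
                    if side == "min":
                        # gate keeps v >= candidate: suffix sums
                        tp_suf = np.cumsum(t_sorted[::-1])[::-1]
                        cnt_suf = np.arange(v_sorted.size, 0, -1, dtype=float)
                        cand_vals = v_sorted[distinct]
                        tp_c = tp_suf[distinct]
                        fp_c = cnt_suf[distinct] - tp_c
                    else:
                        # gate keeps v <= candidate: prefix sums at the
                        # last occurrence of each distinct value
                        tp_pre = np.cumsum(t_sorted)
                        cnt_pre = np.arange(1, v_sorted.size + 1, dtype=float)
                        last = np.ones(v_sorted.size, dtype=bool)
                        last[:-1] = v_sorted[1:] != v_sorted[:-1]
                        cand_vals = v_sorted[last]
                        tp_c = tp_pre[last]
                        fp_c = cnt_pre[last] - tp_c
                    # prepend the unbounded candidate
                    cand_vals = np.concatenate(([np.nan], cand_vals))
                    tp_all = np.concatenate(([t_sorted.sum()], tp_c))
                    fp_all = np.concatenate(([v_sorted.size - t_sorted.sum()], fp_c))
                    f_cand = _f_beta(tp_all, fp_all, n_target, beta)
                    best = int(np.argmax(f_cand))
                    if f_cand[best] > f_cur + tol:
                        if np.isnan(cand_vals[best]):
                            if side == "min":
                                mins[j] = -np.inf
                            else:
                                maxs[j] = np.inf
                        else:
                            if side == "min":
                                mins[j] = cand_vals[best]
                            else:
                                maxs[j] = cand_vals[best]
                        new_f = current_f()
                        if new_f < f_cur - tol:  # pragma: no cover - ascent guard
                            raise RuntimeError("F_beta decreased on an accepted move")
                        f_cur = new_f
                        history.append(f_cur)
                        improved = True
            if not improved:
                break
        return mins, maxs, f_cur

    history: list[float] = []
    mins = np.full(p, -np.inf)
    maxs = np.full(p, np.inf)
    all_channels = list(range(p))
    mins, maxs, f_full = ascend(all_channels, mins, maxs, history)

    bounded = [j for j in all_channels if np.isfinite(mins[j]) or np.isfinite(maxs[j])]
    if not bounded:
        warn("no improving bound found; returning an unbounded gate")

    def f_without(j: int) -> float:
        m2, x2 = mins.copy(), maxs.copy()
        m2[j], x2[j] = -np.inf, np.inf
        mask = np.ones(n, dtype=bool)
        for c in all_channels:
            mask &= (x[:, c] >= m2[c]) & (x[:, c] <= x2[c])
        return float(_f_beta(np.array(np.count_nonzero(mask & target)),
                             np.array(np.count_nonzero(mask & ~target)),
                             n_target, beta))

    contributions = {marker_names[j]: (f_full - f_without(j) if j in bounded else 0.0)
                     for j in all_channels}

    if max_markers is not None and len(bounded) > max_markers:
        ranked = sorted(bounded, key=lambda j: (-contributions[marker_names[j]], j))
        keep = sorted(ranked[:max_markers])
        mins2 = np.full(p, -np.inf)
        maxs2 = np.full(p, np.inf)
        mins2[keep] = mins[keep]
        maxs2[keep] = maxs[keep]
        mins, maxs, f_full = ascend(list(keep), mins2, maxs2, history)

    bounds = []
    for j in range(p):
        if np.isfinite(mins[j]):
            bounds.append(Bound(marker=marker_names[j], bound_type="min", value=float(mins[j])))
        if np.isfinite(maxs[j]):
            bounds.append(Bound(marker=marker_names[j], bound_type="max", value=float(maxs[j])))
    scheme = GatingScheme(kind="hyperrectangle", bounds=bounds, target_population="target")
    return HypergateResult(scheme=scheme, contributions=contributions,
                           f_beta=float(f_full), history=history)


# ---------------------------------------------------------------------------
# Helpers used when preparing training data


def balanced_subsample(labels: np.ndarray, seed: int) -> np.ndarray:
    """Indices of a per-class subsample of size min-class-count, seeded."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    m = int(counts.min())
    picked = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        picked.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(picked))


def split_by_cd34(
    expr: Union[ExpressionMatrix, np.ndarray],
    cd34_marker: str = "CD34",
    cutoff: float = 0.95,
    marker_names: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition cells by normalized CD34 expression > cutoff.

    Returns (positive indices, negative indices). Mirrors the upstream
    FACS enrichment of CD34+ progenitors, so gating schemes are designed
    within the compartment they will be applied to.
    """
    col = _marker_column(expr, cd34_marker, marker_names)
    pos = np.flatnonzero(col > cutoff)
    neg = np.flatnonzero(col <= cutoff)
    if pos.size == 0:
        warn(f"no cells above {cd34_marker} cutoff {cutoff}")
    return pos, neg


def evaluate_expert_scheme(
    predicates: Sequence[tuple[str, str]],
    expr: Union[ExpressionMatrix, np.ndarray],
    truth: np.ndarray,
    marker_names: Optional[Sequence[str]] = None,
    n_bins: int = 256,
    fixed_thresholds: Optional[dict[str, float]] = None,
) -> GateMetrics:
    """Sequential expert gating with Otsu thresholds recomputed per step.

    At each (marker, sign) step the Otsu threshold is computed on the
    events retained so far for that marker; '+' keeps events strictly
    above it, '-' keeps the rest. ``fixed_thresholds`` switches to
    precomputed global thresholds. Errors if a retained set becomes
    degenerate for Otsu, reporting the step index.
    """
    n = (expr.n_cells if isinstance(expr, ExpressionMatrix)
         else np.asarray(expr).shape[0])
    truth = np.asarray(truth)
    if truth.dtype != bool:
        raise ValueError("truth must be a boolean target mask")
    target = truth
    retained = np.ones(n, dtype=bool)
    for step, (marker, sign) in enumerate(predicates):
        if sign not in ("+", "-"):
            raise ValueError(f"step {step}: sign must be '+' or '-'")
        col = _marker_column(expr, marker, marker_names)
        if not retained.any():
            break  # already empty: later predicates cannot change the gate
        if fixed_thresholds is not None:
            t = fixed_thresholds[marker]
        else:
            vals = col[retained]
            try:
                t = otsu_threshold(vals, n_bins=n_bins)
            except ValueError as e:
                raise ValueError(f"step {step} ({marker}{sign}): {e}") from None
        retained = retained & ((col > t) if sign == "+" else (col <= t))
    return _metrics(retained, target)
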