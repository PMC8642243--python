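"""Synthetic atlas / cytometry / abundance data with known ground truth.

The generator emulates the statistical structure the analysis methods
assume, at desk scale:

* a reference atlas with discrete cell types and branching
  differentiation trajectories, antibody-tag counts drawn from a
  negative binomial around per-type (or pseudotime-interpolated) marker
  means, CLR-normalized, with an analytic latent space and 2-D branch
  layout;
* matched cytometry queries drawn from the same populations, passed
  through a per-marker strictly increasing instrument distortion plus
  measurement noise, with true labels retained;
* grouped binomial abundance tables generated under the shared-,
  group- or individual-frequency regime.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .normalize import clr_normalize
from .types import AbundanceData, ExpressionMatrix, QueryCytometry, ReferenceAtlas

__all__ = [
    "Distortion",
    "CellTypeConfig",
    "SimulationConfig",
    "default_config",
    "generate_reference",
    "generate_query",
    "generate_abundance",
]


@dataclass
class Distortion:
    """Strictly increasing per-marker instrument response.

    kinds: ``identity``; ``affine`` (a·x + b, a > 0); ``power`` (x^gamma,
    gamma > 0, on non-negative signal); ``asinh`` (asinh(x / cofactor)).
    """

    kind: str = "identity"
    a: float = 1.0
    b: float = 0.0
    gamma: float = 1.0
    cofactor: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "affine", "power", "asinh"):
            raise ValueError(f"unknown distortion kind {self.kind!r}")
        if self.kind == "affine" and self.a <= 0:
            raise ValueError("affine distortion needs a > 0")
        if self.kind == "power" and self.gamma <= 0:
            raise ValueError("power distortion needs gamma > 0")
        if self.kind == "asinh" and self.cofactor <= 0:
            raise ValueError("asinh distortion needs cofactor > 0")

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            return x
        if self.kind == "affine":
            return self.a * x + self.b
        if self.kind == "power":
            return np.power(np.clip(x, 0.0, None), self.gamma)
        return np.arcsinh(x / self.cofactor)


@dataclass
class CellTypeConfig:
    """One cell population: marker means plus optional trajectory placement."""

    name: str
    frequency: float
    marker_means: np.ndarray  # per-marker mean ADT count for an average-size cell
    pt_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.marker_means = np.asarray(self.marker_means, dtype=float)
        if np.any(self.marker_means < 0):
            raise ValueError(f"{self.name}: marker means must be non-negative")
        lo, hi = self.pt_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"{self.name}: pt_range must satisfy 0 <= lo <= hi <= 1")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    ``branches`` maps trajectory name → ordered list of cell-type names
    from root to tip; marker means are interpolated piecewise-linearly
    in pseudotime between the member types' means. Types in no branch
    are discrete off-trajectory populations.
    """

    markers: list[str]
    cell_types: list[CellTypeConfig]
    branches: dict[str, list[str]] = field(default_factory=dict)
    n_cells: int = 3000
    dispersion: float = 2.0  # NB size parameter; larger = closer to Poisson
    size_factor_sd: float = 0.25  # lognormal sigma of per-cell size factors
    latent_scale: float = 3.0  # separation of population indicator coordinates
    latent_jitter: float = 0.15
    distortions: dict[str, Distortion] = field(default_factory=dict)
    bio_noise_cv: float = 0.2  # lognormal sigma of per-event biological noise
    noise_sd: float = 0.05  # additive measurement noise after distortion
    # abundance regime parameters
    abundance_groups: dict[str, float] = field(
        default_factory=lambda: {"young": 0.05, "aged": 0.5}
    )
    abundance_n_per_group: int = 4
    abundance_total: int = 1000

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        problems = []
        if not self.markers:
            problems.append("no markers")
        names = {t.name for t in self.cell_types}
        if len(names) != len(self.cell_types):
            problems.append("duplicate cell type names")
        freq = sum(t.frequency for t in self.cell_types)
        if not math.isclose(freq, 1.0, rel_tol=1e-6):
            problems.append(f"cell type frequencies sum to {freq}, not 1")
        for t in self.cell_types:
            if len(t.marker_means) != len(self.markers):
                problems.append(f"{t.name}: means length != number of markers")
        for branch, members in self.branches.items():
            unknown = [m for m in members if m not in names]
            if unknown:
                problems.append(f"branch {branch}: unknown types {unknown}")
            if len(members) < 2:
                problems.append(f"branch {branch}: needs at least 2 member types")
        if self.dispersion <= 0:
            problems.append("dispersion must be positive")
        for q in self.abundance_groups.values():
            if not 0.0 <= q <= 1.0:
                problems.append("abundance group frequencies must lie in [0, 1]")
        for m, d in self.distortions.items():
            if m not in self.markers:
                problems.append(f"distortion for unknown marker {m}")
            _ = d  # constructor already validated monotonicity parameters
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    def type_by_name(self, name: str) -> CellTypeConfig:
        for t in self.cell_types:
            if t.name == name:
                return t
        raise KeyError(name)

    def branches_of(self, name: str) -> list[str]:
        return [b for b, members in self.branches.items() if name in members]


def default_config(seed: int = 0) -> SimulationConfig:
    """The packaged small fixture: 6 types, 3 branches, 20 markers, 3,000 cells.

    A stem/progenitor root differentiates along erythroid, myeloid and
    B-lymphoid branches; two mature populations (T, NK) sit off the
    trajectories. Marker means are laid out so each population carries a
    few high markers (well separated), with shared gradients along each
    branch.
    """
    markers = [
        "CD34", "CD38", "CD71", "CD33", "CD19",
        "CD3", "CD56", "CD11a", "CD326", "Tim3",
    ] + [f"M{i:02d}" for i in range(11, 21)]
    p = len(markers)

    def means(**high: float) -> np.ndarray:
        base = np.full(p, 2.0)  # background tag level
        for marker, value in high.items():
            base[markers.index(marker)] = value
        return base

    types = [
        CellTypeConfig("HSC", 0.20, means(CD34=60.0, CD38=5.0, M11=30.0), (0.0, 0.15)),
        CellTypeConfig("Erythroid", 0.16, means(CD71=80.0, CD326=50.0, CD38=30.0, M12=40.0), (0.55, 1.0)),
        CellTypeConfig("Myeloid", 0.16, means(CD33=70.0, Tim3=45.0, CD11a=50.0, CD38=30.0, M13=40.0), (0.55, 1.0)),
        CellTypeConfig("Blymph", 0.16, means(CD19=75.0, CD38=35.0, M14=40.0), (0.55, 1.0)),
        CellTypeConfig("Tcell", 0.16, means(CD3=80.0, CD11a=30.0, M15=40.0)),
        CellTypeConfig("NK", 0.16, means(CD56=75.0, CD11a=30.0, M16=40.0)),
    ]
    branches = {
        "erythroid": ["HSC", "Erythroid"],
        "myeloid": ["HSC", "Myeloid"],
        "blymphoid": ["HSC", "Blymph"],
    }
    distortions = {m: Distortion(kind="asinh", cofactor=5.0) for m in markers}
    return SimulationConfig(
        markers=markers,
        cell_types=types,
        branches=branches,
        distortions=distortions,
    )


# ---------------------------------------------------------------------------
# Shared machinery


def _mean_profile(config: SimulationConfig, type_name: str, pt: float | None) -> np.ndarray:
    """Marker means for a cell of the given type at pseudotime pt.

    On a branch, means are interpolated piecewise-linearly between the
    member types' means anchored at the midpoints of their pt ranges;
    off-trajectory types use their constant means.
    """
    t = config.type_by_name(type_name)
    branches = config.branches_of(type_name)
    if pt is None or not branches:
        return t.marker_means
    branch = branches[0]
    members = [config.type_by_name(m) for m in config.branches[branch]]
    anchors = np.array([0.5 * (m.pt_range[0] + m.pt_range[1]) for m in members])
    profiles = np.stack([m.marker_means for m in members])
    out = np.empty(len(config.markers))
    for j in range(len(config.markers)):
        out[j] = np.interp(pt, anchors, profiles[:, j])
    return out


def _draw_cells(config: SimulationConfig, n: int, rng: np.random.Generator,
                include_types: Optional[Sequence[str]] = None):
    """Sample (type, pseudotime, mean-profile) triples for n cells."""
    if include_types is None:
        types = config.cell_types
    else:
        types = [config.type_by_name(name) for name in include_types]
    freqs = np.array([t.frequency for t in types], dtype=float)
    freqs /= freqs.sum()
    idx = rng.choice(len(types), size=n, p=freqs)
    names, pts, means = [], [], []
    for i in idx:
        t = types[i]
        on_branch = bool(config.branches_of(t.name))
        pt = float(rng.uniform(*t.pt_range)) if on_branch else None
        names.append(t.name)
        pts.append(pt)
        means.append(_mean_profile(config, t.name, pt))
    return np.array(names), pts, np.stack(means)


def _nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial with mean mu and size (dispersion) r; var = mu + mu²/r."""
    r = dispersion
    if np.isinf(r):
        return rng.poisson(mu)
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# Generators


def generate_reference(
    config: SimulationConfig,
    seed: int,
    include_types: Optional[Sequence[str]] = None,
) -> tuple[ReferenceAtlas, pd.DataFrame]:
    """Simulate a CLR-normalized reference atlas plus its ground-truth table.

    ``include_types`` restricts the atlas to a subset of populations
    (frequencies renormalized), e.g. to hold a state out of the
    reference.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_cells
    names, pts, means = _draw_cells(config, n, rng, include_types=include_types)
    sf = rng.lognormal(-0.5 * config.size_factor_sd**2, config.size_factor_sd, size=n)
    counts = _nb_counts(sf[:, None] * means, config.dispersion, rng)

    cell_ids = [f"cell{i:05d}" for i in range(n)]
    raw = ExpressionMatrix(
        values=counts.astype(float),
        feature_names=list(config.markers),
        cell_ids=cell_ids,
        feature_kind="antibody",
        layer="raw_counts",
    )
    normalized = clr_normalize(raw)

    # latent: population indicator coordinates (branch per trajectory cell,
    # own axis per off-trajectory type) plus a pseudotime coordinate.
    branch_names = list(config.branches)
    off_types = [t.name for t in config.cell_types if not config.branches_of(t.name)]
    axes = branch_names + off_types
    d = len(axes) + 1
    latent = np.zeros((n, d))
    embedding = np.zeros((n, 2))
    n_arms = len(axes)
    pt_table = pd.DataFrame(np.nan, index=range(n), columns=branch_names)
    for i in range(n):
        t = names[i]
        my_branches = config.branches_of(t)
        if my_branches:
            for b in my_branches:
                pt_table.loc[i, b] = pts[i]
            arm = axes.index(my_branches[0])
            latent[i, arm] = config.latent_scale
            latent[i, -1] = config.latent_scale * pts[i]
            radius = 0.2 + pts[i]
        else:
            arm = axes.index(t)
            latent[i, arm] = config.latent_scale
            radius = 1.2
        theta = 2.0 * np.pi * arm / n_arms
        embedding[i] = (radius * np.cos(theta), radius * np.sin(theta))
    latent += rng.normal(0.0, config.latent_jitter, size=latent.shape)

    atlas = ReferenceAtlas(
        expr=normalized,
        cell_type=names,
        sample_id=np.array(["sim1"] * n),
        latent=latent,
        embedding=embedding,
        pseudotime=pt_table,
    )
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cell_type": names,
            "pseudotime": [pt if pt is not None else np.nan for pt in pts],
        }
    )
    return atlas, truth


def generate_query(
    config: SimulationConfig,
    n_events: int,
    seed: int,
    include_types: Optional[Sequence[str]] = None,
) -> tuple[QueryCytometry, np.ndarray]:
    """Simulate cytometry events from the configured populations.

    intensity = distortion(mean · biological noise) + measurement noise,
    with the per-marker distortion strictly increasing. Returns the
    query plus the true generating labels. ``include_types`` restricts
    (or reweights) the populations, e.g. to simulate a state absent
    from the atlas.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    names, _, means = _draw_cells(config, n_events, rng, include_types=include_types)
    signal = means * rng.lognormal(
        -0.5 * config.bio_noise_cv**2, config.bio_noise_cv, size=means.shape
    )
    out = np.empty_like(signal)
    for j, marker in enumerate(config.markers):
        dist = config.distortions.get(marker, Distortion())
        out[:, j] = dist.apply(signal[:, j])
    out += rng.normal(0.0, config.noise_sd, size=out.shape)
    query = QueryCytometry(
        intensities=out,
        marker_names=list(config.markers),
        event_ids=[f"event{i:05d}" for i in range(n_events)],
    )
    return query, names


def generate_abundance(
    config: SimulationConfig,
    seed: int,
    regime: str = "M1",
    q: Optional[float] = None,
    individual_q_prior: tuple[float, float] = (1.0, 1.0),
) -> tuple[AbundanceData, str]:
    """Simulate per-individual counts under a frequency-sharing regime.

    ``M0``: one frequency for everyone (``q``, default the mean of the
    configured group frequencies). ``M1``: the configured per-group
    frequencies. ``M2``: per-individual frequencies drawn from
    ``individual_q_prior``. Returns the table and the generating regime
    tag.
    """
    if regime not in ("M0", "M1", "M2"):
        raise ValueError("regime must be M0, M1 or M2")
    rng = np.random.default_rng(seed)
    groups = list(config.abundance_groups)
    m = config.abundance_n_per_group
    total = config.abundance_total
    group_labels = np.repeat(groups, m)
    n = np.full(len(group_labels), total)
    if regime == "M0":
        q0 = float(np.mean(list(config.abundance_groups.values()))) if q is None else q
        qs = np.full(len(group_labels), q0)
    elif regime == "M1":
        qs = np.array([config.abundance_groups[g] for g in group_labels])
    else:
        qs = rng.beta(*individual_q_prior, size=len(group_labels))
    k = rng.binomial(n, qs)
    data = AbundanceData(k=k, n=n, group=group_labels)
    return data, regime
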