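"""File readers and writers: expression matrices, schemes, tables.

Matrices travel as CSV/TSV (cells in rows, header = feature names, first
column = cell id) or MatrixMarket (.mtx plus ``<stem>.features.tsv`` and
``<stem>.barcodes.tsv`` sidecars). Gating schemes are JSON with a
round-trippable schema. Output tables carry a leading ``#`` comment line
recording the tool version and effective parameters.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .gating import Bound, GatingScheme, TreeLeaf, TreeSplit
from .types import AbundanceData, ExpressionMatrix, QueryCytometry, ReferenceAtlas

__all__ = [
    "read_expression",
    "write_expression",
    "read_query",
    "read_atlas",
    "write_atlas",
    "read_scheme",
    "write_scheme",
    "read_abundance",
    "write_table",
]


def _header_comment(**params) -> str:
    parts = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# cytoref v{__version__}" + (f" {parts}" if parts else "")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "tsv", "mtx"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_expression(
    path: Union[str, Path],
    format: Optional[str] = None,
    layer: str = "raw_counts",
    feature_kind: str = "antibody",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Load a cells × features matrix from CSV/TSV or MatrixMarket.

    For ``mtx``, sidecar files ``<stem>.features.tsv`` and
    ``<stem>.barcodes.tsv`` must sit next to the matrix. ``transpose``
    handles feature-major exports.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        # check the raw header before pandas mangles duplicate names
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    header = [h.strip() for h in line.rstrip("\n").split(sep)][1:]
                    break
            else:
                raise ValueError(f"{path}: empty file")
        if not transpose and len(set(header)) != len(header):
            dups = sorted({h for h in header if header.count(h) > 1})
            raise ValueError(f"{path}: duplicate feature columns {dups}")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        except Exception as e:
            raise ValueError(f"malformed {fmt} file {path}: {e}") from None
        if transpose:
            df = df.T
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate feature columns {dups}")
        values = df.to_numpy(dtype=float)
        features = [str(c) for c in df.columns]
        cells = [str(i) for i in df.index]
    else:
        feat_path = path.parent / (path.stem + ".features.tsv")
        bc_path = path.parent / (path.stem + ".barcodes.tsv")
        for p in (feat_path, bc_path):
            if not p.exists():
                raise ValueError(f"missing MatrixMarket sidecar file {p}")
        mat = spio.mmread(path)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        if transpose:
            values = values.T
        features = feat_path.read_text().splitlines()
        cells = bc_path.read_text().splitlines()
        if values.shape != (len(cells), len(features)):
            raise ValueError(
                f"{path}: matrix shape {values.shape} does not match sidecars "
                f"({len(cells)} barcodes × {len(features)} features)"
            )
    return ExpressionMatrix(
        values=values,
        feature_names=features,
        cell_ids=cells,
        feature_kind=feature_kind,
        layer=layer,
    )


def write_expression(expr: ExpressionMatrix, path: Union[str, Path],
                     format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        expr.to_frame().to_csv(path, sep=sep, index_label="cell_id")
    else:
        spio.mmwrite(path, sparse.coo_matrix(expr.values))
        (path.parent / (path.stem + ".features.tsv")).write_text(
            "\n".join(expr.feature_names) + "\n")
        (path.parent / (path.stem + ".barcodes.tsv")).write_text(
            "\n".join(expr.cell_ids) + "\n")


def read_query(path: Union[str, Path], format: Optional[str] = None) -> QueryCytometry:
    """Load an events × markers intensity table (transformed scale)."""
    expr = read_expression(path, format=format, layer="normalized")
    return QueryCytometry(
        intensities=expr.values,
        marker_names=list(expr.feature_names),
        event_ids=list(expr.cell_ids),
    )


def read_atlas(expr_path: Union[str, Path], meta_path: Union[str, Path],
               format: Optional[str] = None) -> ReferenceAtlas:
    """Assemble a ReferenceAtlas from an expression matrix and a metadata TSV.

    The metadata table is keyed by cell id and must provide ``cell_type``,
    ``sample_id``, latent columns ``latent_*``, ``embedding_x``/
    ``embedding_y`` and zero or more ``pseudotime_<trajectory>`` columns.
    """
    expr = read_expression(expr_path, format=format, layer="normalized")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, comment="#")
    meta.index = meta.index.astype(str)
    missing = [c for c in expr.cell_ids if c not in meta.index]
    if missing:
        raise ValueError(f"metadata missing {len(missing)} cell id(s), e.g. {missing[:3]}")
    meta = meta.loc[expr.cell_ids]
    latent_cols = sorted(c for c in meta.columns if c.startswith("latent_"))
    pt_cols = [c for c in meta.columns if c.startswith("pseudotime_")]
    for col in ("cell_type", "sample_id", "embedding_x", "embedding_y"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if not latent_cols:
        raise ValueError("metadata has no latent_* columns")
    pt = meta[pt_cols].copy()
    pt.columns = [c[len("pseudotime_"):] for c in pt_cols]
    return ReferenceAtlas(
        expr=expr,
        cell_type=meta["cell_type"].to_numpy(),
        sample_id=meta["sample_id"].to_numpy(),
        latent=meta[latent_cols].to_numpy(dtype=float),
        embedding=meta[["embedding_x", "embedding_y"]].to_numpy(dtype=float),
        pseudotime=pt.reset_index(drop=True),
    )


def write_atlas(atlas: ReferenceAtlas, outdir: Union[str, Path]) -> tuple[Path, Path]:
    """Write expression (CSV) and metadata (TSV) for round-tripping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_path = outdir / "atlas_expression.csv"
    meta_path = outdir / "atlas_metadata.tsv"
    write_expression(atlas.expr, expr_path)
    meta = pd.DataFrame({"cell_type": atlas.cell_type, "sample_id": atlas.sample_id},
                        index=pd.Index(atlas.expr.cell_ids, name="cell_id"))
    for d in range(atlas.latent.shape[1]):
        meta[f"latent_{d:02d}"] = atlas.latent[:, d]
    meta["embedding_x"] = atlas.embedding[:, 0]
    meta["embedding_y"] = atlas.embedding[:, 1]
    for traj in atlas.pseudotime.columns:
        meta[f"pseudotime_{traj}"] = atlas.pseudotime[traj].to_numpy()
    meta.to_csv(meta_path, sep="\t")
    return expr_path, meta_path


# ---------------------------------------------------------------------------
# Gating scheme JSON


def _tree_to_json(node):
    if isinstance(node, TreeLeaf):
        return {"leaf": True, "label": node.label}
    return {
        "leaf": False,
        "marker": node.marker,
        "threshold": node.threshold,
        "left": _tree_to_json(node.left),
        "right": _tree_to_json(node.right),
    }


def _tree_from_json(obj, pointer: str = "/nodes"):
    if not isinstance(obj, dict) or "leaf" not in obj:
        raise ValueError(f"schema error at {pointer}: expected a node object")
    if obj["leaf"]:
        if "label" not in obj or obj["label"] in (None, ""):
            raise ValueError(f"schema error at {pointer}: unlabeled leaf")
        return TreeLeaf(label=str(obj["label"]))
    for key in ("marker", "threshold", "left", "right"):
        if key not in obj:
            raise ValueError(f"schema error at {pointer}: missing {key!r}")
    return TreeSplit(
        marker=str(obj["marker"]),
        threshold=float(obj["threshold"]),
        left=_tree_from_json(obj["left"], pointer + "/left"),
        right=_tree_from_json(obj["right"], pointer + "/right"),
    )


def write_scheme(scheme: GatingScheme, path: Union[str, Path]) -> None:
    obj: dict = {"kind": scheme.kind, "version": __version__}
    if scheme.kind == "tree":
        obj["nodes"] = _tree_to_json(scheme.tree)
    elif scheme.kind == "hyperrectangle":
        obj["bounds"] = [
            {"marker": b.marker, "bound_type": b.bound_type, "value": b.value}
            for b in scheme.bounds
        ]
    else:
        obj["predicates"] = [{"marker": m, "sign": s} for m, s in scheme.predicates]
    if scheme.target_population is not None:
        obj["population"] = scheme.target_population
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_scheme(path: Union[str, Path]) -> GatingScheme:
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed scheme JSON {path}: {e}") from None
    kind = obj.get("kind")
    if kind not in ("tree", "hyperrectangle", "expert"):
        raise ValueError(f"schema error at /kind: unknown kind {kind!r}")
    population = obj.get("population")
    if kind == "tree":
        return GatingScheme(kind="tree", tree=_tree_from_json(obj.get("nodes")),
                            target_population=population)
    if kind == "hyperrectangle":
        bounds = []
        for i, b in enumerate(obj.get("bounds", [])):
            for key in ("marker", "bound_type", "value"):
                if key not in b:
                    raise ValueError(f"schema error at /bounds/{i}: missing {key!r}")
            bounds.append(Bound(marker=str(b["marker"]), bound_type=str(b["bound_type"]),
                                value=float(b["value"])))
        return GatingScheme(kind="hyperrectangle", bounds=bounds,
                            target_population=population)
    predicates = []
    for i, p in enumerate(obj.get("predicates", [])):
        if "marker" not in p or "sign" not in p:
            raise ValueError(f"schema error at /predicates/{i}: need marker and sign")
        predicates.append((str(p["marker"]), str(p["sign"])))
    return GatingScheme(kind="expert", predicates=predicates, target_population=population)


# ---------------------------------------------------------------------------
# Tables


def read_abundance(path: Union[str, Path]) -> AbundanceData:
    """Read a counts CSV: individual_id, group, target_count, total_count."""
    df = pd.read_csv(path, comment="#")
    required = {"individual_id", "group", "target_count", "total_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return AbundanceData(
        k=df["target_count"].to_numpy(),
        n=df["total_count"].to_numpy(),
        group=df["group"].to_numpy(),
        individual_id=df["individual_id"].to_numpy(),
    )


def write_table(df: pd.DataFrame, path: Union[str, Path], sep: str = "\t", **params) -> None:
    """Write a table with a leading comment line (tool version + parameters)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_comment(**params) + "\n")
        df.to_csv(fh, sep=sep, index=False)
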