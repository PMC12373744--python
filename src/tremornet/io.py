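"""Readers and writers for morphometry tables, atlases and networks.

Supported table dialects: CSV, TSV, and the whitespace "stats" dialect used
by surface-reconstruction pipelines (comment lines starting with ``#``; the
``# ColHeaders`` line declares the column names of the fixed-width records
that follow).  Structure names are canonicalized to ``<Name>.<Hemi>`` with
hemisphere in {L, R}; ``Left-``/``Right-`` prefixes are accepted synonyms.
"""

from __future__ import annotations

import json
import math
import os
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .core import SCORE_NAMES, MorphometryDataset, SubjectMetadata, SurfaceAtlas
from .errors import AlignmentError, FormatError, UsageError, ValidationError

TABLE_DIALECTS = ("csv", "tsv", "freesurfer_stats")
NETWORK_FORMATS = ("graphml", "dot", "edge_list")


def canonical_structure(name: str) -> str:
    """Map ``Left-Pallidum``-style names onto the canonical ``Pallidum.L``."""
    if name.startswith("Left-"):
        return f"{name[len('Left-'):]}.L"
    if name.startswith("Right-"):
        return f"{name[len('Right-'):]}.R"
    return name


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_morphometry_table(path, dialect: str = "csv") -> pd.DataFrame:
    """Read a subjects-x-columns (or structures-x-columns) table.

    For ``freesurfer_stats`` the single file describes one subject: rows are
    structures, columns come from the ``# ColHeaders`` declaration, and the
    returned frame is indexed by canonical structure name.
    """
    if dialect not in TABLE_DIALECTS:
        raise UsageError(f"unknown dialect {dialect!r}; choose from {TABLE_DIALECTS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        try:
            table = pd.read_csv(path, sep=sep)
        except pd.errors.EmptyDataError:
            raise FormatError(f"{path}: empty file") from None
        first = table.columns[0]
        if table[first].duplicated().any():
            dups = table[first][table[first].duplicated()].tolist()
            raise FormatError(f"{path}: duplicate ids in column {first!r}: {dups}")
        return table
    return _read_stats_file(path)


def _read_stats_file(path: Path) -> pd.DataFrame:
    colheaders: Optional[list[str]] = None
    records: list[list[str]] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: empty file")
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("ColHeaders"):
                colheaders = body.split()[1:]
                if not colheaders:
                    raise FormatError(
                        f"{path}:{lineno}: '# ColHeaders' declares no columns"
                    )
            continue
        records.append(stripped.split())
    if colheaders is None:
        raise FormatError(f"{path}: no '# ColHeaders' line found")
    for lineno, rec in enumerate(records, start=1):
        if len(rec) != len(colheaders):
            raise FormatError(
                f"{path}: record {lineno} has {len(rec)} fields, "
                f"expected {len(colheaders)} ({' '.join(rec)})"
            )
    table = pd.DataFrame(records, columns=colheaders)
    for col in table.columns:
        if col != "StructName":
            table[col] = pd.to_numeric(table[col], errors="coerce")
    if "StructName" in table.columns:
        names = table["StructName"].map(canonical_structure)
        if names.duplicated().any():
            dups = names[names.duplicated()].tolist()
            raise FormatError(f"{path}: duplicate structure names: {dups}")
        table = table.drop(columns=["StructName"])
        table.index = names
        table.index.name = "StructName"
    return table


def write_stats_file(volumes_row: pd.Series, path, value_col: str = "Volume_mm3") -> None:
    """Write one subject's structure volumes in the stats dialect."""
    with open(path, "w") as fh:
        fh.write("# Table of structure volumes\n")
        fh.write(f"# ColHeaders Index StructName {value_col}\n")
        for i, (name, value) in enumerate(volumes_row.items(), start=1):
            fh.write(f"{i} {name} {float(value)!r}\n")


def read_volume_table(path, dialect: str = "csv") -> pd.DataFrame:
    """Cohort-level volume table: wide CSV/TSV, or a directory of per-subject
    ``<subject_id>.stats`` files for the freesurfer_stats dialect."""
    if dialect in ("csv", "tsv"):
        table = read_morphometry_table(path, dialect)
        table = table.set_index(table.columns[0])
        table.index.name = "subject_id"
        table.columns = [canonical_structure(c) for c in table.columns]
        return table
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"{path}: freesurfer_stats cohort input must be a directory")
    rows = {}
    for stats in sorted(path.glob("*.stats")):
        table = _read_stats_file(stats)
        value_cols = [c for c in table.columns if c not in ("Index",)]
        if not value_cols:
            raise FormatError(f"{stats}: no value column declared")
        rows[stats.stem] = table[value_cols[-1]]
    if not rows:
        raise FormatError(f"{path}: no .stats files found")
    out = pd.DataFrame(rows).T
    out.index.name = "subject_id"
    return out


def write_volume_table(volumes: pd.DataFrame, path, dialect: str = "csv") -> None:
    if dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        volumes.to_csv(path, sep=sep, index_label="subject_id")
        return
    os.makedirs(path, exist_ok=True)
    for sid, row in volumes.iterrows():
        write_stats_file(row, Path(path) / f"{sid}.stats")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = ["subject_id", "group", "age", "sex", "education", "duration", "hy_stage"]


def metadata_to_frame(subjects: Iterable[SubjectMetadata]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "education": s.education,
            "duration": s.duration,
            "hy_stage": s.hy_stage,
        }
        for name in SCORE_NAMES:
            row[name] = s.scores.get(name)
        rows.append(row)
    return pd.DataFrame(rows, columns=_META_COLUMNS + list(SCORE_NAMES))


def metadata_from_frame(table: pd.DataFrame) -> list[SubjectMetadata]:
    def _opt(v):
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else v

    subjects = []
    for _, row in table.iterrows():
        hy = _opt(row.get("hy_stage"))
        subjects.append(
            SubjectMetadata(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=_opt(row.get("education")),
                duration=_opt(row.get("duration")),
                hy_stage=None if hy is None else int(hy),
                scores={k: _opt(row.get(k)) for k in SCORE_NAMES},
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def assemble_dataset(
    thickness_table: pd.DataFrame,
    volume_table: pd.DataFrame,
    metadata_table: pd.DataFrame,
    atlas: SurfaceAtlas,
) -> MorphometryDataset:
    """Align the three tables by subject id and build a validated dataset.

    The thickness table's first column (or index) holds subject ids; the
    remaining columns are vertices in atlas order.
    """
    thick = thickness_table
    if "subject_id" in thick.columns:
        thick = thick.set_index("subject_id")
    elif thick.index.name != "subject_id":
        thick = thick.set_index(thick.columns[0])
    vols = volume_table
    if "subject_id" in vols.columns:
        vols = vols.set_index("subject_id")
    subjects = metadata_from_frame(metadata_table)
    meta_ids = [s.subject_id for s in subjects]

    sets = {
        "thickness": set(map(str, thick.index)),
        "volumes": set(map(str, vols.index)),
        "metadata": set(meta_ids),
    }
    union = set.union(*sets.values())
    inter = set.intersection(*sets.values())
    if union != inter:
        detail = {
            name: sorted(union - ids) for name, ids in sets.items() if union - ids
        }
        raise AlignmentError(f"subject ids disagree; missing per table: {detail}")

    thick = thick.loc[meta_ids]
    vols = vols.loc[meta_ids]
    vols.columns = [canonical_structure(c) for c in vols.columns]
    thickness = thick.to_numpy(dtype=float)
    if np.any(~np.isfinite(thickness)) or np.any(thickness <= 0):
        raise ValidationError("thickness table contains missing or non-positive values")
    return MorphometryDataset(
        atlas=atlas, thickness=thickness, volumes=vols, subjects=subjects
    )


def write_dataset(dataset: MorphometryDataset, outdir, dialect: str = "csv") -> dict:
    """Write thickness/volumes/metadata tables (+ atlas) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sep = "\t" if dialect == "tsv" else ","
    ext = "tsv" if dialect == "tsv" else "csv"
    paths = {}

    thick = pd.DataFrame(
        dataset.thickness,
        index=pd.Index(dataset.subject_ids, name="subject_id"),
        columns=[f"v{i}" for i in range(dataset.atlas.n_vertices)],
    )
    paths["thickness"] = outdir / f"thickness.{ext}"
    thick.to_csv(paths["thickness"], sep=sep)

    if dialect == "freesurfer_stats":
        paths["volumes"] = outdir / "volumes_stats"
        write_volume_table(dataset.volumes, paths["volumes"], dialect)
    else:
        paths["volumes"] = outdir / f"volumes.{ext}"
        write_volume_table(dataset.volumes, paths["volumes"], "csv" if ext == "csv" else "tsv")

    paths["metadata"] = outdir / f"metadata.{ext}"
    metadata_to_frame(dataset.subjects).to_csv(paths["metadata"], sep=sep, index=False)

    paths["atlas"] = outdir / "atlas.json"
    write_atlas(dataset.atlas, paths["atlas"])
    return paths


def read_dataset(indir, dialect: str = "csv") -> MorphometryDataset:
    indir = Path(indir)
    ext = "tsv" if dialect == "tsv" else "csv"
    sep = "\t" if dialect == "tsv" else ","
    atlas = read_atlas(indir / "atlas.json")
    thick = pd.read_csv(indir / f"thickness.{ext}", sep=sep)
    if dialect == "freesurfer_stats":
        vols = read_volume_table(indir / "volumes_stats", "freesurfer_stats")
    else:
        vols = read_volume_table(indir / f"volumes.{ext}", dialect)
    meta = pd.read_csv(indir / f"metadata.{ext}", sep=sep)
    return assemble_dataset(thick, vols, meta, atlas)


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def write_atlas(atlas: SurfaceAtlas, path) -> None:
    payload = {
        "region_names": list(atlas.region_names),
        "region_of_vertex": atlas.region_of_vertex.tolist(),
        "edges": atlas.edges.tolist(),
        "grid_shape": list(atlas.grid_shape) if atlas.grid_shape else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_atlas(path) -> SurfaceAtlas:
    with open(path) as fh:
        payload = json.load(fh)
    return SurfaceAtlas(
        edges=np.asarray(payload["edges"], dtype=np.int64).reshape(-1, 2),
        region_of_vertex=np.asarray(payload["region_of_vertex"], dtype=np.int64),
        region_names=payload["region_names"],
        grid_shape=tuple(payload["grid_shape"]) if payload["grid_shape"] else None,
    )


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def network_to_digraph(network) -> nx.DiGraph:
    """Directed graph view of a CausalNetwork (edges where adjacency is 1,
    or every finite off-diagonal weight when no adjacency is set)."""
    g = nx.DiGraph()
    nodes = list(network.nodes)
    g.add_nodes_from(nodes)
    k = len(nodes)
    adj = network.adjacency
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            w = network.weights[i, j]
            if adj is not None:
                if adj[i, j]:
                    g.add_edge(nodes[i], nodes[j], weight=float(w))
            elif np.isfinite(w):
                g.add_edge(nodes[i], nodes[j], weight=float(w))
    return g


def write_network(network, path, format: str = "graphml") -> None:
    """Serialize a CausalNetwork; graphml and edge_list round-trip losslessly."""
    if format not in NETWORK_FORMATS:
        raise UsageError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    g = network_to_digraph(network)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge_list":
        with open(path, "w") as fh:
            for node in g.nodes:
                fh.write(f"# node {node}\n")
            for u, v, data in g.edges(data=True):
                fh.write(f"{u} {v} {data['weight']!r}\n")
    else:  # dot (write-only; no extra dependency for reading)
        with open(path, "w") as fh:
            fh.write("digraph causal {\n")
            for node in g.nodes:
                fh.write(f'  "{node}";\n')
            for u, v, data in g.edges(data=True):
                fh.write(f'  "{u}" -> "{v}" [weight={data["weight"]!r}];\n')
            fh.write("}\n")


def read_network(path, format: str = "graphml"):
    from .cascn import CausalNetwork  # local import to avoid a cycle

    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = list(g.nodes)
        edges = [(u, v, float(d["weight"])) for u, v, d in g.edges(data=True)]
    elif format == "edge_list":
        nodes, edges = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("# node "):
                    nodes.append(line[len("# node "):])
                elif not line.startswith("#"):
                    u, v, w = line.split()
                    edges.append((u, v, float(w)))
    else:
        raise UsageError(f"reading format {format!r} is not supported")
    k = len(nodes)
    index = {n: i for i, n in enumerate(nodes)}
    weights = np.full((k, k), np.nan)
    adjacency = np.zeros((k, k), dtype=int)
    for u, v, w in edges:
        weights[index[u], index[v]] = w
        adjacency[index[u], index[v]] = 1
    return CausalNetwork(nodes=tuple(nodes), weights=weights, adjacency=adjacency)
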