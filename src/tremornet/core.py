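"""Domain types shared by every analysis stage.

The atlas is an abstract labeled graph: vertices, an undirected adjacency,
and a partition of the vertices into named, connected regions.  No surface
geometry is carried; every spatial operation in the package (smoothing,
cluster extraction, random-field inference) is defined on the graph, with a
fast path when the graph is a 2D grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .errors import NamingError, UsageError, ValidationError

GROUPS = ("TD", "ET", "HC")
SEXES = ("M", "F")
SCORE_NAMES = ("MoCA", "MMSE", "HAM_A", "HAM_D", "VHI")

#: Structures every volume table must carry (canonical "<Name>.<Hemi>" form).
REQUIRED_STRUCTURES = ("Pallidum.L", "Pallidum.R", "Thalamus.L", "Thalamus.R")


class SurfaceAtlas:
    """Labeled vertex graph standing in for a cortical parcellation.

    Parameters
    ----------
    edges : (m, 2) int array
        Undirected edges; each row is one vertex pair.  Symmetry is implied
        (each unordered pair is stored once); self-edges are rejected.
    region_of_vertex : (n,) int array
        Index into ``region_names`` for every vertex.
    region_names : sequence of str
        Ordered region names; every name must own at least one vertex.
    grid_shape : (rows, cols), optional
        Set when the graph is a 4-connected 2D lattice in row-major vertex
        order; enables fast array-based smoothing and labeling.
    """

    def __init__(
        self,
        edges: np.ndarray,
        region_of_vertex: np.ndarray,
        region_names: Sequence[str],
        grid_shape: Optional[tuple[int, int]] = None,
        validate: bool = True,
    ):
        self.edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        self.region_of_vertex = np.asarray(region_of_vertex, dtype=np.int64)
        self.region_names = tuple(str(r) for r in region_names)
        self.grid_shape = tuple(grid_shape) if grid_shape is not None else None
        self._adjacency: Optional[sparse.csr_matrix] = None
        if validate:
            self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return int(self.region_of_vertex.size)

    @property
    def vertex_ids(self) -> np.ndarray:
        return np.arange(self.n_vertices)

    def region_index(self, region: str) -> int:
        try:
            return self.region_names.index(region)
        except ValueError:
            raise NamingError(
                f"unknown region {region!r}; known regions: {list(self.region_names)}"
            ) from None

    def vertices_of(self, region: str) -> np.ndarray:
        """All vertex ids belonging to ``region``."""
        return np.flatnonzero(self.region_of_vertex == self.region_index(region))

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric boolean adjacency as CSR (built lazily, cached)."""
        if self._adjacency is None:
            n = self.n_vertices
            i = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
            j = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
            a = sparse.coo_matrix(
                (np.ones(i.size, dtype=np.int8), (i, j)), shape=(n, n)
            )
            self._adjacency = a.tocsr()
        return self._adjacency

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n = self.n_vertices
        if n == 0:
            raise ValidationError("atlas has no vertices")
        if self.edges.size and (
            self.edges.min() < 0 or self.edges.max() >= n
        ):
            raise ValidationError("edge endpoint outside vertex range")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValidationError("atlas adjacency contains self-edges")
        if self.region_of_vertex.min(initial=0) < 0 or self.region_of_vertex.max(
            initial=0
        ) >= len(self.region_names):
            raise ValidationError("vertex maps to an unknown region index")
        counts = np.bincount(self.region_of_vertex, minlength=len(self.region_names))
        empty = [r for r, c in zip(self.region_names, counts) if c == 0]
        if empty:
            raise ValidationError(f"regions with no vertices: {empty}")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValidationError("duplicate region names")
        adj = self.adjacency()
        for ri, name in enumerate(self.region_names):
            idx = np.flatnonzero(self.region_of_vertex == ri)
            sub = adj[idx][:, idx]
            n_comp, _ = connected_components(sub, directed=False)
            if n_comp != 1:
                raise ValidationError(
                    f"region {name!r} is not connected ({n_comp} components)"
                )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SurfaceAtlas):
            return NotImplemented
        return (
            np.array_equal(self.edges, other.edges)
            and np.array_equal(self.region_of_vertex, other.region_of_vertex)
            and self.region_names == other.region_names
            and self.grid_shape == other.grid_shape
        )

    def __repr__(self) -> str:
        return (
            f"SurfaceAtlas(n_vertices={self.n_vertices}, "
            f"n_regions={len(self.region_names)}, grid_shape={self.grid_shape})"
        )


@dataclass
class SubjectMetadata:
    """Demographics and clinical state of one subject.

    ``duration`` is required for patients (TD/ET) and must be absent for HC
    callers that have no duration concept; clinical scores may be absent for
    HC (explicit ``None``, never a sentinel number).
    """

    subject_id: str
    group: str
    age: float
    sex: str
    education: Optional[float] = None
    duration: Optional[float] = None
    hy_stage: Optional[int] = None
    scores: Mapping[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(
                f"subject {self.subject_id}: group {self.group!r} not in {GROUPS}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"subject {self.subject_id}: sex {self.sex!r} not in {SEXES}"
            )
        if self.group != "HC":
            if self.duration is None:
                raise ValidationError(
                    f"subject {self.subject_id}: duration required for {self.group}"
                )
        if self.duration is not None and self.duration < 0:
            raise ValidationError(
                f"subject {self.subject_id}: negative duration {self.duration}"
            )


@dataclass
class MorphometryDataset:
    """Aligned per-subject morphometry: thickness matrix + volume table.

    Row order of ``thickness`` and ``volumes`` equals the order of
    ``subjects``; thickness is strictly positive with no missing entries.
    """

    atlas: SurfaceAtlas
    thickness: np.ndarray          # subjects x vertices, mm
    volumes: pd.DataFrame          # subjects x structures, mm^3
    subjects: list[SubjectMetadata]

    def __post_init__(self):
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects], dtype=float)

    @property
    def sexes(self) -> np.ndarray:
        """Sex coded numerically: M=0, F=1."""
        return np.array([SEXES.index(s.sex) for s in self.subjects], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        """Disease duration in years; NaN where absent (HC)."""
        return np.array(
            [np.nan if s.duration is None else s.duration for s in self.subjects],
            dtype=float,
        )

    def group_mask(self, *groups: str) -> np.ndarray:
        for g in groups:
            if g not in GROUPS:
                raise UsageError(f"unknown group {g!r}")
        return np.isin(self.groups, groups)

    def subset(self, selector) -> "MorphometryDataset":
        """New dataset restricted to a boolean mask or index array."""
        idx = np.asarray(selector)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return MorphometryDataset(
            atlas=self.atlas,
            thickness=self.thickness[idx],
            volumes=self.volumes.iloc[idx],
            subjects=[self.subjects[i] for i in idx],
        )

    def region_means(self, regions: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Per-subject mean thickness for each region (mm)."""
        regions = list(regions) if regions is not None else list(self.atlas.region_names)
        cols = {}
        for r in regions:
            cols[r] = self.thickness[:, self.atlas.vertices_of(r)].mean(axis=1)
        return pd.DataFrame(cols, index=self.subject_ids)

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, v = self.thickness.shape
        if n != len(self.subjects):
            raise ValidationError(
                f"thickness has {n} rows but {len(self.subjects)} subjects"
            )
        if v != self.atlas.n_vertices:
            raise ValidationError(
                f"thickness has {v} columns but atlas has {self.atlas.n_vertices} vertices"
            )
        if not np.all(np.isfinite(self.thickness)):
            raise ValidationError("thickness contains missing/non-finite entries")
        if np.any(self.thickness <= 0):
            i, j = np.argwhere(self.thickness <= 0)[0]
            raise ValidationError(
                f"non-positive thickness at subject {self.subjects[i].subject_id}, "
                f"vertex {j}: {self.thickness[i, j]}"
            )
        if list(self.volumes.index) != self.subject_ids:
            raise ValidationError("volume table row order differs from subjects order")
        missing = [s for s in REQUIRED_STRUCTURES if s not in self.volumes.columns]
        if missing:
            raise ValidationError(f"volume table missing structures: {missing}")
        ids = self.subject_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids")


@dataclass
class StatMap:
    """Per-vertex statistic map with its p-values.

    ``kind`` is one of ``t``, ``z``, ``gc``; p-values live in (0, 1].
    """

    statistic: np.ndarray
    p: np.ndarray
    df: float
    kind: str = "t"

    def __post_init__(self):
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.kind not in ("t", "z", "gc"):
            raise ValidationError(f"unknown stat kind {self.kind!r}")
        if self.statistic.shape != self.p.shape:
            raise ValidationError("statistic and p lengths differ")
        if np.any(self.p <= 0) or np.any(self.p > 1):
            raise ValidationError("p-values must lie in (0, 1]")

    @property
    def n_vertices(self) -> int:
        return int(self.statistic.size)


@dataclass
class Cluster:
    """One connected supra-threshold component."""

    vertices: np.ndarray
    peak_vertex: int
    peak_stat: float
    corrected_p: float

    @property
    def size(self) -> int:
        return int(self.vertices.size)

    @property
    def sign(self) -> int:
        return int(np.sign(self.peak_stat)) or 1


@dataclass
class ClusterResult:
    """Clusters from one corrected vertex-wise analysis."""

    clusters: list[Cluster]
    alpha: float = 0.05
    method: str = ""

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.corrected_p < self.alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "size": c.size,
                "peak_vertex": c.peak_vertex,
                "peak_stat": c.peak_stat,
                "corrected_p": c.corrected_p,
                "significant": c.corrected_p < self.alpha,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows, columns=["size", "peak_vertex", "peak_stat", "corrected_p", "significant"]
        )
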