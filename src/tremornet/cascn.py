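"""Causal structural covariance networks on duration-ordered pseudo-time.

Patients of one group are sorted by ascending disease duration (ties broken
by subject id) to form a pseudo-time series per vertex or region.  Directed
influence is quantified by the signed path coefficient of a bivariate
first-order Granger model: for source x and target y,

    y_t = a + b y_{t-1} + c x_{t-1} + e_t,

and the reported quantity is the signed coefficient c.  Vertex-wise maps
keep only positive coefficients, standardize them to z-scores, and control
familywise error by permuting the duration ordering (max-statistic null).
ROI-to-ROI coefficients are assembled into a directed weighted network whose
binary in/out-degrees identify source and target hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Cluster, ClusterResult, MorphometryDataset, StatMap
from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateDataError,
    NamingError,
    UsageError,
    ValidationError,
)
from .fields import label_components
from .groupdiff import _TINY_P


@dataclass
class PseudoTimeSeries:
    """One region/vertex series over duration-ordered patients."""

    subject_ids: tuple[str, ...]
    durations: np.ndarray
    values: np.ndarray
    group: str = ""
    name: str = ""

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.subject_ids) == self.durations.size == self.values.size):
            raise ValidationError("pseudo-time series fields have unequal lengths")
        if np.any(np.diff(self.durations) < 0):
            raise ValidationError("durations must be non-decreasing along the series")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class GCResult:
    """Signed path coefficient with its test; z is filled when the value is
    standardized across a map or matrix."""

    coefficient: float
    p: float
    n_effective: int
    z: float = float("nan")
    t_stat: float = float("nan")


@dataclass
class CausalNetwork:
    """Directed weighted ROI graph; adjacency/degrees appear after
    thresholding."""

    nodes: tuple[str, ...]
    weights: np.ndarray                       # z-scored GC, diagonal NaN
    adjacency: Optional[np.ndarray] = None    # binary directed
    coefficients: Optional[np.ndarray] = None # raw signed path coefficients
    z_threshold: Optional[float] = None
    group: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        k = len(self.nodes)
        if self.weights.shape != (k, k):
            raise ValidationError("weight matrix shape does not match node count")

    @property
    def out_degree(self) -> np.ndarray:
        if self.adjacency is None:
            raise UsageError("network not thresholded yet; call threshold_network")
        return self.adjacency.sum(axis=1)

    @property
    def in_degree(self) -> np.ndarray:
        if self.adjacency is None:
            raise UsageError("network not thresholded yet; call threshold_network")
        return self.adjacency.sum(axis=0)

    def degree_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"out_degree": self.out_degree, "in_degree": self.in_degree},
            index=pd.Index(self.nodes, name="region"),
        )

    def hubs(self) -> dict:
        out_deg, in_deg = self.out_degree, self.in_degree
        return {
            "out_hub": self.nodes[int(np.argmax(out_deg))],
            "out_degree": int(out_deg.max()),
            "in_hub": self.nodes[int(np.argmax(in_deg))],
            "in_degree": int(in_deg.max()),
        }


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

def duration_order(dataset: MorphometryDataset, group: str) -> np.ndarray:
    """Indices (into the dataset) of ``group`` patients sorted by ascending
    duration, ties broken by ascending subject id."""
    if group == "HC":
        raise UsageError("HC has no disease duration; pseudo-time is undefined")
    if group not in ("TD", "ET"):
        raise UsageError(f"unknown patient group {group!r}")
    idx = np.flatnonzero(dataset.group_mask(group))
    if idx.size == 0:
        raise UsageError(f"no {group} subjects in dataset")
    durations = dataset.durations[idx]
    ids = np.array([dataset.subjects[i].subject_id for i in idx])
    order = np.lexsort((ids, durations))
    return idx[order]


def _detrend(values: np.ndarray, covs: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(values.shape[0]), covs])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta + values.mean(axis=0)


def build_pseudo_series(
    dataset: MorphometryDataset,
    group: str,
    values: np.ndarray,
    detrend_covariates: bool = False,
    name: str = "",
) -> PseudoTimeSeries:
    """Order per-subject ``values`` (aligned with the dataset) into a
    duration-ordered pseudo-time series for one patient group.

    With ``detrend_covariates`` age and sex are regressed out of the values
    (within the group) before ordering.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != dataset.n_subjects:
        raise AlignmentError(
            f"values has {values.shape[0]} entries for {dataset.n_subjects} subjects"
        )
    order = duration_order(dataset, group)
    v = values[order]
    if detrend_covariates:
        covs = np.column_stack([dataset.ages[order], dataset.sexes[order]])
        v = _detrend(v if v.ndim > 1 else v[:, None], covs)
        if values.ndim == 1:
            v = v.ravel()
    return PseudoTimeSeries(
        subject_ids=tuple(dataset.subjects[i].subject_id for i in order),
        durations=dataset.durations[order],
        values=v,
        group=group,
        name=name,
    )


def region_pseudo_series(
    dataset: MorphometryDataset, group: str, region: str,
    detrend_covariates: bool = False,
) -> PseudoTimeSeries:
    vertices = dataset.atlas.vertices_of(region)
    return build_pseudo_series(
        dataset, group, dataset.thickness[:, vertices].mean(axis=1),
        detrend_covariates=detrend_covariates, name=region,
    )


# ---------------------------------------------------------------------------
# signed-path Granger causality
# ---------------------------------------------------------------------------

def signed_path_gca(x: PseudoTimeSeries, y: PseudoTimeSeries, order: int = 1) -> GCResult:
    """Signed path coefficient of x's first lag on y.

    Fits ``y_t = a + sum_l b_l y_{t-l} + sum_l c_l x_{t-l}`` by OLS over
    t = order+1 .. T and reports c_1 with its two-sided t-test p-value.
    Self-causality (x identical to y) is undefined and rejected.
    """
    if x.subject_ids != y.subject_ids:
        raise AlignmentError("x and y pseudo-series have different subject orderings")
    if np.array_equal(x.values, y.values):
        raise UsageError("self-causality (x identical to y) is undefined")
    T = len(y)
    if T <= order + 2:
        raise UsageError(f"series length {T} too short for order {order}")
    if np.std(x.values) == 0 or np.std(y.values) == 0:
        raise DegenerateDataError("constant pseudo-time series")

    yv, xv = y.values, x.values
    return _gca_arrays(xv, yv, order)


def _gca_arrays(xv: np.ndarray, yv: np.ndarray, order: int) -> GCResult:
    T = yv.size
    target = yv[order:]
    cols = [np.ones(T - order)]
    for lag in range(1, order + 1):
        cols.append(yv[order - lag:T - lag])
    for lag in range(1, order + 1):
        cols.append(xv[order - lag:T - lag])
    X = np.column_stack(cols)
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        raise DegenerateDataError("degenerate lag design (collinear series)") from None
    beta = xtx_inv @ X.T @ target
    resid = target - X @ beta
    df = (T - order) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    c_index = 1 + order  # first x lag
    c = float(beta[c_index])
    se = float(np.sqrt(sigma2 * xtx_inv[c_index, c_index]))
    t = c / se if se > 0 else np.inf
    p = float(np.clip(2.0 * stats.t.sf(abs(t), df), _TINY_P, 1.0))
    return GCResult(coefficient=c, p=p, n_effective=T - order, t_stat=t)


def _gc_all_vertices(V: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized order-1 signed-path GC from one source onto every column.

    ``V`` is the (T, n_vertices) duration-ordered value matrix, ``x`` the
    (T,) source series.  Returns per-vertex (coefficient, t-statistic).
    """
    T, nv = V.shape
    y = V[1:]         # targets at t
    yl = V[:-1]       # their own lag
    xl = x[:-1]       # source lag
    n = T - 1
    one = np.ones(n)

    # normal-equation moments per vertex: design [1, y_{t-1}, x_{t-1}]
    s_y = yl.sum(axis=0)
    s_x = float(xl.sum())
    s_yy = np.einsum("tv,tv->v", yl, yl)
    s_xx = float(xl @ xl)
    s_xy = xl @ yl
    XtX = np.empty((nv, 3, 3))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = s_y
    XtX[:, 0, 2] = XtX[:, 2, 0] = s_x
    XtX[:, 1, 1] = s_yy
    XtX[:, 1, 2] = XtX[:, 2, 1] = s_xy
    XtX[:, 2, 2] = s_xx

    Xty = np.empty((nv, 3))
    Xty[:, 0] = one @ y
    Xty[:, 1] = np.einsum("tv,tv->v", yl, y)
    Xty[:, 2] = xl @ y

    XtX_inv = np.linalg.inv(XtX)
    beta = np.einsum("vij,vj->vi", XtX_inv, Xty)
    yty = np.einsum("tv,tv->v", y, y)
    rss = yty - np.einsum("vi,vi->v", beta, Xty)
    df = n - 3
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 * XtX_inv[:, 2, 2])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[:, 2] / se, 0.0)
    return beta[:, 2], t


def vertexwise_cascn(
    dataset: MorphometryDataset,
    group: str,
    seed_region: str,
    order: int = 1,
    alpha: float = 0.05,
    min_cluster: int = 10,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    detrend_covariates: bool = False,
) -> tuple[StatMap, ClusterResult]:
    """Seed-to-vertex causal map with permutation familywise control.

    Negative coefficients are discarded; survivors are standardized to
    z-scores across the retained vertices.  Corrected per-vertex p-values
    come from the max-statistic distribution over ``n_perm`` shuffles of the
    duration ordering, and significant vertices are grouped into connected
    clusters of which only those with size strictly greater than
    ``min_cluster`` are kept.
    """
    if order != 1:
        raise ConfigurationError("vertex-wise maps support model order 1 only")
    if n_perm < 100:
        raise ConfigurationError(f"n_perm must be >= 100, got {n_perm}")
    atlas = dataset.atlas
    seed_vertices = atlas.vertices_of(seed_region)
    ordering = duration_order(dataset, group)
    if ordering.size < 10:
        raise UsageError(f"group {group} has {ordering.size} patients; need >= 10")

    V = dataset.thickness[ordering]
    if detrend_covariates:
        covs = np.column_stack([dataset.ages[ordering], dataset.sexes[ordering]])
        V = _detrend(V, covs)
    x = V[:, seed_vertices].mean(axis=1)
    coef, t_obs = _gc_all_vertices(V, x)
    coef[seed_vertices] = 0.0  # self-causality undefined
    t_obs[seed_vertices] = 0.0

    rng = np.random.default_rng(seed)
    T = V.shape[0]
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(T)
        _, t_null = _gc_all_vertices(V[perm], x[perm])
        t_null[seed_vertices] = -np.inf
        null_max[b] = t_null.max()
    exceed = (null_max[None, :] >= t_obs[:, None]).sum(axis=1)
    corrected_p = np.clip((1.0 + exceed) / (n_perm + 1.0), _TINY_P, 1.0)

    retained = coef > 0
    z = np.zeros_like(coef)
    if retained.sum() >= 2:
        vals = coef[retained]
        sd = vals.std()
        z[retained] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    elif not retained.any():
        warnings.warn("all GC coefficients negative; empty causal map", stacklevel=2)

    significant = retained & (corrected_p < alpha)
    clusters = []
    labels, n_lab = label_components(significant, atlas)
    for lab in range(1, n_lab + 1):
        vertices = np.flatnonzero(labels == lab)
        if vertices.size <= min_cluster:  # strictly greater than min_cluster
            continue
        stats_here = z[vertices]
        peak_local = int(np.argmax(stats_here))
        clusters.append(
            Cluster(vertices=vertices, peak_vertex=int(vertices[peak_local]),
                    peak_stat=float(stats_here[peak_local]),
                    corrected_p=float(corrected_p[vertices].min()))
        )
    clusters.sort(key=lambda c: -c.size)
    stat_map = StatMap(statistic=z, p=corrected_p, df=float(T - 1 - 3), kind="gc")
    return stat_map, ClusterResult(clusters=clusters, alpha=alpha, method="cascn_perm")


def roi_cascn_matrix(
    dataset: MorphometryDataset,
    group: str,
    rois: Sequence[str],
    order: int = 1,
    detrend_covariates: bool = False,
    weight_kind: str = "coef_z",
) -> CausalNetwork:
    """ROI-to-ROI signed path coefficients assembled into a directed matrix.

    ``weight_kind='coef_z'`` (default) standardizes the raw coefficients
    across the off-diagonal entries; ``'t'`` uses each coefficient's
    parametric t-statistic instead, which is scale-free and separates
    genuine lead-lag influence from shared-trend coupling far better on
    strongly trended pseudo-series.
    """
    rois = list(rois)
    if len(rois) < 2:
        raise NamingError(f"need at least 2 ROIs, got {len(rois)}")
    if len(set(rois)) != len(rois):
        dups = sorted({r for r in rois if rois.count(r) > 1})
        raise NamingError(f"duplicate ROI names: {dups}")
    if weight_kind not in ("coef_z", "t"):
        raise UsageError(f"unknown weight kind {weight_kind!r}")
    series = {
        r: region_pseudo_series(dataset, group, r, detrend_covariates)
        for r in rois
    }
    k = len(rois)
    coefs = np.full((k, k), np.nan)
    tstats = np.full((k, k), np.nan)
    for i, src in enumerate(rois):
        for j, tgt in enumerate(rois):
            if i == j:
                continue
            res = signed_path_gca(series[src], series[tgt], order=order)
            coefs[i, j] = res.coefficient
            tstats[i, j] = res.t_stat
    off = ~np.eye(k, dtype=bool)
    weights = np.full((k, k), np.nan)
    if weight_kind == "coef_z":
        vals = coefs[off]
        sd = vals.std()
        weights[off] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    else:
        weights[off] = tstats[off]
    return CausalNetwork(
        nodes=tuple(rois), weights=weights, coefficients=coefs, group=group
    )


def threshold_network(network: CausalNetwork, z_threshold: float = 1.0) -> CausalNetwork:
    """Binarize: edge i->j iff weight >= z_threshold and positive."""
    if z_threshold < 0:
        warnings.warn(
            "negative z-threshold with a positive-only edge convention",
            stacklevel=2,
        )
    w = network.weights
    adjacency = np.where(np.isnan(w), 0, (w >= z_threshold) & (w > 0)).astype(int)
    np.fill_diagonal(adjacency, 0)
    return CausalNetwork(
        nodes=network.nodes,
        weights=network.weights,
        adjacency=adjacency,
        coefficients=network.coefficients,
        z_threshold=z_threshold,
        group=network.group,
    )
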