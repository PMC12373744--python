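"""Seed-based structural covariance networks.

Group differences in seed-vertex thickness covariance are tested with a
seed x group interaction GLM (covariate-adjusted); a Fisher-z correlation
difference is exposed as a cross-check.  Cluster-level inference uses the
Gaussian-random-field extent approximation, with a permutation fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import Cluster, ClusterResult, MorphometryDataset, StatMap, SurfaceAtlas
from .errors import DegenerateDataError, UsageError, ValidationError
from .fields import estimate_fwhm, label_components
from .groupdiff import _TINY_P, cluster_correct_mcs, ols_tmap


@dataclass
class SeedSeries:
    """Per-subject mean thickness over one seed region (mm)."""

    region: str
    values: np.ndarray
    subject_ids: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.subject_ids):
            raise ValidationError("seed series length differs from subject count")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("seed series contains non-finite values")


@dataclass
class SmoothnessEstimate:
    """Field smoothness: FWHM in vertex units plus the implied resel count."""

    fwhm: float
    resels: float

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValidationError("FWHM must be positive")


def extract_seed(dataset: MorphometryDataset, region: str) -> SeedSeries:
    """Mean thickness over the region's vertices, one value per subject."""
    vertices = dataset.atlas.vertices_of(region)  # raises NamingError if unknown
    return SeedSeries(
        region=region,
        values=dataset.thickness[:, vertices].mean(axis=1),
        subject_ids=tuple(dataset.subject_ids),
    )


def scn_interaction_map(
    dataset: MorphometryDataset,
    seed: SeedSeries,
    group_pair: tuple[str, str] = ("TD", "HC"),
    covariates: Sequence[str] = ("age", "sex"),
    exclude_seed_region: bool = True,
) -> tuple[MorphometryDataset, StatMap]:
    """Seed x group interaction t-map over the two groups.

    At each vertex fits ``thickness = b0 + b1 seed + b2 group + b3 seed*group
    (+ covariates)`` with the patient group coded 1, and returns the t-map of
    b3: a negative t means seed-target covariance is lower in patients than
    in the comparison group.  Seed-region vertices are excluded from the
    target set (t forced to 0, p to 1) unless disabled.
    """
    patient, other = group_pair
    mask = dataset.group_mask(patient, other)
    if tuple(seed.subject_ids) != tuple(dataset.subject_ids):
        raise UsageError("seed series was not extracted from this dataset")
    sub = dataset.subset(mask)
    s = seed.values[mask]
    g = (sub.groups == patient).astype(float)
    if not g.any() or g.all():
        raise UsageError(f"both groups of {group_pair} must be non-empty")
    for grp_val in (0.0, 1.0):
        if np.std(s[g == grp_val]) == 0:
            raise DegenerateDataError(
                f"seed {seed.region} is constant within one group; interaction undefined"
            )
    s_c = s - s.mean()  # center to decorrelate main effect and interaction
    cols = [np.ones(sub.n_subjects), s_c, g, s_c * g]
    names = ["intercept", "seed", "group", "seed_x_group"]
    pools = {"age": sub.ages, "sex": sub.sexes}
    for cov in covariates:
        cols.append(pools[cov])
        names.append(cov)
    X = np.column_stack(cols)
    c = np.zeros(X.shape[1])
    c[3] = 1.0
    t, df = ols_tmap(sub.thickness, X, c)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), _TINY_P, 1.0)
    if exclude_seed_region:
        own = dataset.atlas.vertices_of(seed.region)
        t[own] = 0.0
        p[own] = 1.0
    return sub, StatMap(statistic=t, p=p, df=df, kind="t")


def scn_correlation_difference(
    dataset: MorphometryDataset,
    seed: SeedSeries,
    group_pair: tuple[str, str] = ("TD", "HC"),
) -> StatMap:
    """Cross-check: Fisher-z difference of seed-vertex correlations."""
    patient, other = group_pair
    if tuple(seed.subject_ids) != tuple(dataset.subject_ids):
        raise UsageError("seed series was not extracted from this dataset")
    zs, ns = [], []
    for grp in (patient, other):
        m = dataset.group_mask(grp)
        th = dataset.thickness[m]
        s = seed.values[m]
        s_std = s.std()
        if s_std == 0:
            raise DegenerateDataError(f"seed constant within group {grp}")
        sc = (s - s.mean()) / s_std
        th_c = th - th.mean(axis=0)
        denom = th_c.std(axis=0) * math.sqrt(th.shape[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, (sc @ th_c) / (denom * math.sqrt(th.shape[0])), 0.0)
        r = np.clip(r, -0.999999, 0.999999)
        zs.append(np.arctanh(r))
        ns.append(th.shape[0])
    z = (zs[0] - zs[1]) / math.sqrt(1.0 / (ns[0] - 3) + 1.0 / (ns[1] - 3))
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), _TINY_P, 1.0)
    return StatMap(statistic=z, p=p, df=float(ns[0] + ns[1] - 6), kind="z")


def estimate_smoothness(residual_maps: np.ndarray, atlas: SurfaceAtlas) -> SmoothnessEstimate:
    """Field smoothness from nearest-neighbor residual differences."""
    residual_maps = np.atleast_2d(np.asarray(residual_maps, dtype=float))
    if residual_maps.shape[0] < 2:
        raise UsageError("smoothness estimation needs at least 2 residual maps")
    fwhm = estimate_fwhm(residual_maps, atlas)
    return SmoothnessEstimate(fwhm=fwhm, resels=atlas.n_vertices / fwhm**2)


# ---------------------------------------------------------------------------
# GRF cluster-level inference
# ---------------------------------------------------------------------------

def grf_cluster_p(
    size: int, z_thresh: float, resels: float, n_vertices: int
) -> float:
    """Cluster-level corrected p for a 2D Gaussian field.

    Expected-cluster formulation: the number of clusters above threshold u
    is approximated by E[m] = R (4 ln 2) (2 pi)^(-3/2) u exp(-u^2/2) per
    sign (R = resels); the expected cluster size in vertices is
    E[n] = N Phi(-u) / E[m]; cluster extent is taken exponential for D=2,
    P(n >= k) = exp(-k / E[n]); and the corrected p is the Poisson-clumping
    bound 1 - exp(-2 E[m] P(n >= k)) with both signs counted.
    """
    u = float(z_thresh)
    em1 = resels * (4.0 * math.log(2.0)) * (2.0 * math.pi) ** -1.5 * u * math.exp(
        -(u**2) / 2.0
    )
    if em1 <= 0:
        return 1.0
    en = n_vertices * stats.norm.sf(u) / em1
    p_extent = math.exp(-size / en) if en > 0 else 0.0
    corrected = 1.0 - math.exp(-2.0 * em1 * p_extent)
    return float(min(1.0, max(_TINY_P, corrected)))


def grf_cluster_correct(
    stat_map: StatMap,
    atlas: SurfaceAtlas,
    smoothness: SmoothnessEstimate,
    cluster_forming_p: float = 0.01,
    alpha: float = 0.05,
    method: str = "grf",
    n_iter: int = 1000,
    seed: Optional[int] = None,
) -> ClusterResult:
    """Cluster-level correction via GRF extent approximation.

    ``method='permutation'`` reuses the Monte-Carlo machinery (smooth
    Gaussian null fields at the estimated smoothness) instead of the
    analytic approximation.
    """
    if cluster_forming_p >= 0.05 and method == "grf":
        warnings.warn(
            "GRF extent approximation is poor at cluster-forming p >= 0.05",
            stacklevel=2,
        )
    if method == "permutation":
        return cluster_correct_mcs(
            stat_map, atlas, cluster_forming_p=cluster_forming_p, alpha=alpha,
            n_iter=n_iter, seed=seed, fwhm=smoothness.fwhm,
        )
    z_u = stats.norm.isf(cluster_forming_p / 2.0)
    supra = stat_map.p < cluster_forming_p
    clusters = []
    for sign in (1, -1):
        mask = supra & (np.sign(stat_map.statistic) == sign)
        labels, n = label_components(mask, atlas)
        for lab in range(1, n + 1):
            vertices = np.flatnonzero(labels == lab)
            stats_here = stat_map.statistic[vertices]
            peak_local = int(np.argmax(np.abs(stats_here)))
            corrected = grf_cluster_p(
                vertices.size, z_u, smoothness.resels, atlas.n_vertices
            )
            clusters.append(
                Cluster(vertices=vertices, peak_vertex=int(vertices[peak_local]),
                        peak_stat=float(stats_here[peak_local]), corrected_p=corrected)
            )
    clusters.sort(key=lambda c: (c.corrected_p, -c.size))
    return ClusterResult(clusters=clusters, alpha=alpha, method="grf")
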