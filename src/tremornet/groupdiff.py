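"""Group morphometry: vertex-wise GLM with Monte-Carlo cluster correction,
subcortical ANCOVA with FDR + Bonferroni post-hoc, summary-statistic tests,
and forward-inference binomial enrichment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Cluster, ClusterResult, MorphometryDataset, StatMap, SurfaceAtlas
from .errors import (
    ConfigurationError,
    DesignError,
    NamingError,
    UsageError,
    ValidationError,
)
from .fields import estimate_fwhm, label_components, smooth_fields

_TINY_P = 1e-300  # keeps p-values inside (0, 1]


@dataclass
class DesignMatrix:
    """OLS design with a named contrast over its columns."""

    matrix: np.ndarray
    columns: list[str]
    contrast: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.matrix.shape[1] != len(self.columns):
            raise DesignError("column names do not match matrix width")
        if self.contrast.size != self.matrix.shape[1]:
            raise DesignError("contrast length differs from column count")

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def make_group_design(
    dataset: MorphometryDataset,
    groups: tuple[str, str] = ("TD", "HC"),
    covariates: Sequence[str] = ("age", "sex"),
) -> tuple[MorphometryDataset, DesignMatrix]:
    """Two-group contrast design (first group coded 1) plus covariates.

    Returns the dataset restricted to the two groups together with the
    aligned design; the contrast tests group1 - group2.
    """
    sub = dataset.subset(dataset.group_mask(*groups))
    cols = [np.ones(sub.n_subjects), (sub.groups == groups[0]).astype(float)]
    names = ["intercept", f"{groups[0]}_vs_{groups[1]}"]
    pools = {"age": sub.ages, "sex": sub.sexes,
             "education": np.array([s.education or 0.0 for s in sub.subjects])}
    for cov in covariates:
        if cov not in pools:
            raise DesignError(f"unknown covariate {cov!r}")
        cols.append(pools[cov])
        names.append(cov)
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return sub, DesignMatrix(matrix=X, columns=names, contrast=contrast)


def _check_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [columns[i] for i in range(X.shape[1])
               if abs(r[i, i]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise DesignError(f"design is rank deficient; collinear columns: {bad}")


def ols_tmap(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-column OLS t statistic for ``contrast`` on responses ``Y`` (n x v)."""
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - np.linalg.matrix_rank(X)
    sigma2 = np.sum(resid**2, axis=0) / df
    var_c = float(contrast @ xtx_inv @ contrast)
    denom = np.sqrt(var_c * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (contrast @ beta) / denom, 0.0)
    return t, float(df)


def fit_vertex_glm(
    dataset: MorphometryDataset,
    design: DesignMatrix,
    contrast: Optional[np.ndarray] = None,
) -> StatMap:
    """Vertex-wise OLS t-map for a contrast, with two-sided p-values."""
    X = design.matrix
    if X.shape[0] != dataset.n_subjects:
        raise DesignError(
            f"design has {X.shape[0]} rows but dataset has {dataset.n_subjects} subjects"
        )
    _check_rank(X, design.columns)
    c = design.contrast if contrast is None else np.asarray(contrast, dtype=float)
    t, df = ols_tmap(dataset.thickness, X, c)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), _TINY_P, 1.0)
    return StatMap(statistic=t, p=p, df=df, kind="t")


def residual_maps(dataset: MorphometryDataset, design: DesignMatrix) -> np.ndarray:
    """OLS residuals of the thickness matrix under the design (n x v)."""
    X = design.matrix
    beta = np.linalg.pinv(X) @ dataset.thickness
    return dataset.thickness - X @ beta


# ---------------------------------------------------------------------------
# Monte-Carlo cluster correction
# ---------------------------------------------------------------------------

def _observed_clusters(stat_map: StatMap, atlas: SurfaceAtlas, cluster_forming_p: float):
    """Sign-split supra-threshold components of the observed map."""
    clusters = []
    supra = stat_map.p < cluster_forming_p
    for sign in (1, -1):
        mask = supra & (np.sign(stat_map.statistic) == sign)
        labels, n = label_components(mask, atlas)
        for lab in range(1, n + 1):
            vertices = np.flatnonzero(labels == lab)
            stats_here = stat_map.statistic[vertices]
            peak_local = int(np.argmax(np.abs(stats_here)))
            clusters.append(
                (vertices, int(vertices[peak_local]), float(stats_here[peak_local]))
            )
    return clusters


def null_max_cluster_sizes(
    atlas: SurfaceAtlas,
    fwhm: float,
    cluster_forming_p: float,
    n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Max supra-threshold cluster size per synthesized smooth Gaussian field.

    Fields are white noise smoothed to ``fwhm``, standardized, and
    thresholded two-sidedly at the same vertex-forming p as the observed
    map; sizes are taken per sign so each null cluster is single-signed.
    """
    z_u = stats.norm.isf(cluster_forming_p / 2.0)
    fields = smooth_fields(rng.standard_normal((n_iter, atlas.n_vertices)), atlas, fwhm)
    fields -= fields.mean(axis=1, keepdims=True)
    fields /= fields.std(axis=1, keepdims=True)
    out = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        pos = np.count_nonzero(fields[i] > z_u)
        neg = np.count_nonzero(fields[i] < -z_u)
        best = 0
        if pos:
            labels, nl = label_components(fields[i] > z_u, atlas)
            if nl:
                best = int(np.bincount(labels[labels > 0]).max())
        if neg:
            labels, nl = label_components(fields[i] < -z_u, atlas)
            if nl:
                best = max(best, int(np.bincount(labels[labels > 0]).max()))
        out[i] = best
    return out


def cluster_correct_mcs(
    stat_map: StatMap,
    atlas: SurfaceAtlas,
    cluster_forming_p: float = 0.01,
    alpha: float = 0.05,
    n_iter: int = 1000,
    seed: Optional[int] = None,
    fwhm: Optional[float] = None,
) -> ClusterResult:
    """Monte-Carlo cluster-wise correction of a vertex-wise map.

    The null distribution of the maximum cluster size is built from
    synthesized Gaussian fields smoothed to the smoothness estimated from
    the observed map (unless ``fwhm`` overrides it).  Corrected p follows
    the add-one permutation convention (1 + #{null >= size}) / (n_iter + 1).
    """
    if n_iter < 100:
        raise ConfigurationError(f"n_iter must be >= 100 for a stable tail, got {n_iter}")
    if stat_map.n_vertices != atlas.n_vertices:
        raise ValidationError("stat map length differs from atlas vertex count")
    observed = _observed_clusters(stat_map, atlas, cluster_forming_p)
    if not observed:
        return ClusterResult(clusters=[], alpha=alpha, method="mcs")
    if fwhm is None:
        fwhm = estimate_fwhm(stat_map.statistic[None, :], atlas)
    rng = np.random.default_rng(seed)
    null_max = null_max_cluster_sizes(atlas, fwhm, cluster_forming_p, n_iter, rng)
    clusters = []
    for vertices, peak, peak_stat in observed:
        exceed = int(np.count_nonzero(null_max >= vertices.size))
        corrected = (1.0 + exceed) / (n_iter + 1.0)
        clusters.append(
            Cluster(vertices=vertices, peak_vertex=peak, peak_stat=peak_stat,
                    corrected_p=corrected)
        )
    clusters.sort(key=lambda c: (c.corrected_p, -c.size))
    return ClusterResult(clusters=clusters, alpha=alpha, method="mcs")


def cluster_correct_permutation(
    dataset: MorphometryDataset,
    design: DesignMatrix,
    atlas: SurfaceAtlas,
    cluster_forming_p: float = 0.01,
    alpha: float = 0.05,
    n_iter: int = 1000,
    seed: Optional[int] = None,
) -> ClusterResult:
    """Assumption-light alternative: permute group labels, rebuild the t-map,
    and use the permuted max-cluster-size distribution as the null."""
    if n_iter < 100:
        raise ConfigurationError(f"n_iter must be >= 100, got {n_iter}")
    stat_map = fit_vertex_glm(dataset, design)
    observed = _observed_clusters(stat_map, atlas, cluster_forming_p)
    if not observed:
        return ClusterResult(clusters=[], alpha=alpha, method="permutation")
    rng = np.random.default_rng(seed)
    group_col = int(np.flatnonzero(design.contrast)[0])
    null_max = np.empty(n_iter, dtype=np.int64)
    X = design.matrix.copy()
    for b in range(n_iter):
        Xp = X.copy()
        Xp[:, group_col] = rng.permutation(X[:, group_col])
        t, df = ols_tmap(dataset.thickness, Xp, design.contrast)
        p = np.clip(2.0 * stats.t.sf(np.abs(t), df), _TINY_P, 1.0)
        perm_map = StatMap(statistic=t, p=p, df=df, kind="t")
        sizes = [v.size for v, _, _ in _observed_clusters(perm_map, atlas, cluster_forming_p)]
        null_max[b] = max(sizes) if sizes else 0
    clusters = []
    for vertices, peak, peak_stat in observed:
        exceed = int(np.count_nonzero(null_max >= vertices.size))
        clusters.append(
            Cluster(vertices=vertices, peak_vertex=peak, peak_stat=peak_stat,
                    corrected_p=(1.0 + exceed) / (n_iter + 1.0))
        )
    clusters.sort(key=lambda c: (c.corrected_p, -c.size))
    return ClusterResult(clusters=clusters, alpha=alpha, method="permutation")


# ---------------------------------------------------------------------------
# subcortical ANCOVA
# ---------------------------------------------------------------------------

@dataclass
class PosthocTable:
    """Per-structure F tests with FDR across structures and Bonferroni
    pairwise contrasts for structures passing FDR < alpha."""

    table: pd.DataFrame
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


_PAIRS = (("TD", "ET"), ("TD", "HC"), ("ET", "HC"))


def subcortical_ancova(
    dataset: MorphometryDataset,
    covariates: Sequence[str] = ("age", "sex"),
    structures: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> PosthocTable:
    """Group ANCOVA per structure, BH-FDR across structures, Bonferroni
    post-hoc pairwise contrasts (adjusted p = min(1, 3 * p))."""
    groups = dataset.groups
    present = [g for g in ("TD", "ET", "HC") if np.any(groups == g)]
    if len(present) < 3:
        raise UsageError(f"ANCOVA needs all three groups, found {present}")
    for g in present:
        if np.count_nonzero(groups == g) < 3:
            raise UsageError(f"group {g} has fewer than 3 subjects")
    if structures is None:
        structures = list(dataset.volumes.columns)
    missing = [s for s in structures if s not in dataset.volumes.columns]
    if missing:
        raise NamingError(f"structures absent from the volume table: {missing}")

    pools = {"age": dataset.ages, "sex": dataset.sexes}
    covs = []
    for cov in covariates:
        if cov in pools:
            covs.append(pools[cov])
        elif cov in dataset.volumes.columns:  # e.g. estimated intracranial volume
            covs.append(dataset.volumes[cov].to_numpy(dtype=float))
        else:
            raise DesignError(f"unknown covariate {cov!r}")
    # group dummies: TD and ET indicators against the HC baseline
    d_td = (groups == "TD").astype(float)
    d_et = (groups == "ET").astype(float)
    n = dataset.n_subjects
    X_full = np.column_stack([np.ones(n), d_td, d_et] + covs)
    X_red = np.column_stack([np.ones(n)] + covs)
    _check_rank(X_full, ["intercept", "TD", "ET"] + list(covariates))

    rows = []
    df_num = 2
    df_den = n - np.linalg.matrix_rank(X_full)
    for struct in structures:
        y = dataset.volumes[struct].to_numpy(dtype=float)
        rss_full = _rss(y, X_full)
        rss_red = _rss(y, X_red)
        if rss_full <= 0:
            f_stat, p_raw = np.inf, _TINY_P
        else:
            f_stat = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
            p_raw = float(np.clip(stats.f.sf(f_stat, df_num, df_den), _TINY_P, 1.0))
        rows.append({"structure": struct, "F": float(f_stat), "p_raw": p_raw})
    table = pd.DataFrame(rows).set_index("structure")
    table["p_fdr"] = bh_adjust(table["p_raw"].to_numpy())

    # pairwise Bonferroni contrasts for FDR survivors
    for a, b in _PAIRS:
        table[f"p_{a}_{b}"] = np.nan
        table[f"dir_{a}_{b}"] = ""
    xtx_inv = np.linalg.inv(X_full.T @ X_full)
    contrasts = {("TD", "ET"): np.array([0.0, 1.0, -1.0] + [0.0] * len(covs)),
                 ("TD", "HC"): np.array([0.0, 1.0, 0.0] + [0.0] * len(covs)),
                 ("ET", "HC"): np.array([0.0, 0.0, 1.0] + [0.0] * len(covs))}
    for struct in structures:
        if table.loc[struct, "p_fdr"] >= alpha:
            continue
        y = dataset.volumes[struct].to_numpy(dtype=float)
        beta = xtx_inv @ X_full.T @ y
        sigma2 = _rss(y, X_full) / df_den
        for (a, b), c in contrasts.items():
            est = float(c @ beta)
            se = float(np.sqrt(c @ xtx_inv @ c * sigma2))
            t = est / se if se > 0 else np.inf
            p_pair = float(np.clip(2.0 * stats.t.sf(abs(t), df_den), _TINY_P, 1.0))
            table.loc[struct, f"p_{a}_{b}"] = bonferroni_adjust(p_pair, 3)
            table.loc[struct, f"dir_{a}_{b}"] = f"{a}>{b}" if est > 0 else f"{a}<{b}"
    return PosthocTable(table=table, alpha=alpha)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p_values = np.asarray(p_values, dtype=float)
    _, adj, _, _ = multipletests(p_values, method="fdr_bh")
    return adj


def bonferroni_adjust(p: float, n_comparisons: int = 3) -> float:
    """Bonferroni-adjusted p: min(1, n * p)."""
    return min(1.0, n_comparisons * p)


# ---------------------------------------------------------------------------
# summary-statistic tests
# ---------------------------------------------------------------------------

def summary_stat_tests(
    rows: Mapping[str, Mapping[str, tuple[float, float, int]]],
    test: str = "welch_t",
) -> pd.DataFrame:
    """Group tests computed from (mean, sd, n) summaries alone.

    ``rows`` maps variable -> group -> (mean, sd, n).  ``welch_t`` and
    ``student_t`` require exactly two groups; ``oneway_anova`` accepts two
    or more and uses the standard between/within decomposition.
    """
    if test not in ("welch_t", "student_t", "oneway_anova"):
        raise UsageError(f"unknown test {test!r}")
    out = []
    for var, per_group in rows.items():
        stats_list = list(per_group.values())
        for mean, sd, n in stats_list:
            if n < 2:
                raise UsageError(f"{var}: group n must be >= 2")
            if sd <= 0:
                raise UsageError(f"{var}: group sd must be > 0")
        if test in ("welch_t", "student_t"):
            if len(stats_list) != 2:
                raise UsageError(f"{var}: t-tests need exactly 2 groups, got {len(stats_list)}")
            (m1, s1, n1), (m2, s2, n2) = stats_list
            res = stats.ttest_ind_from_stats(
                m1, s1, n1, m2, s2, n2, equal_var=(test == "student_t")
            )
            out.append({"variable": var, "statistic": float(res.statistic),
                        "p": float(res.pvalue)})
        else:
            means = np.array([m for m, _, _ in stats_list])
            sds = np.array([s for _, s, _ in stats_list])
            ns = np.array([n for _, _, n in stats_list], dtype=float)
            grand = np.sum(ns * means) / np.sum(ns)
            ss_between = np.sum(ns * (means - grand) ** 2)
            ss_within = np.sum((ns - 1) * sds**2)
            df_b = len(stats_list) - 1
            df_w = np.sum(ns) - len(stats_list)
            f_stat = (ss_between / df_b) / (ss_within / df_w)
            out.append({"variable": var, "statistic": float(f_stat),
                        "p": float(stats.f.sf(f_stat, df_b, df_w))})
    return pd.DataFrame(out).set_index("variable")


# ---------------------------------------------------------------------------
# forward-inference binomial enrichment
# ---------------------------------------------------------------------------

def forward_inference_binomial(
    activation_counts: Mapping[str, tuple[int, int]],
    base_rate: float,
) -> pd.DataFrame:
    """One-sided exact binomial enrichment per domain, BH across domains."""
    if not 0.0 < base_rate < 1.0:
        raise ValidationError(f"base_rate must be in (0, 1), got {base_rate}")
    rows = []
    for domain, (k, n) in activation_counts.items():
        if not 0 <= k <= n:
            raise ValidationError(f"{domain}: need 0 <= k <= n, got k={k}, n={n}")
        p = float(stats.binom.sf(k - 1, n, base_rate))  # P(X >= k)
        rows.append({"domain": domain, "k": k, "n": n, "p": p})
    table = pd.DataFrame(rows).set_index("domain")
    table["p_fdr"] = bh_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# early-stage subgroup filters
# ---------------------------------------------------------------------------

EARLY_STAGE_RULES = ("td_hy_le2", "et_duration_lt10")


def early_stage_filter(dataset: MorphometryDataset, rule: str) -> MorphometryDataset:
    """Early-stage subgroup: early TD has H-Y stage <= 2; early ET has
    duration strictly below 10 years.  HC subjects are retained unchanged."""
    if rule not in EARLY_STAGE_RULES:
        raise UsageError(f"unknown rule {rule!r}; choose from {EARLY_STAGE_RULES}")
    groups = dataset.groups
    if rule == "td_hy_le2":
        if not np.any(groups == "TD"):
            raise UsageError("rule td_hy_le2 requires TD subjects in the dataset")
        keep = np.array([
            (s.group == "HC")
            or (s.group == "TD" and s.hy_stage is not None and s.hy_stage <= 2)
            for s in dataset.subjects
        ])
    else:
        if not np.any(groups == "ET"):
            raise UsageError("rule et_duration_lt10 requires ET subjects in the dataset")
        keep = np.array([
            (s.group == "HC")
            or (s.group == "ET" and s.duration is not None and s.duration < 10.0)
            for s in dataset.subjects
        ])
    if not np.any(keep & (groups != "HC")):
        warnings.warn(f"early-stage rule {rule} retained no patients", stacklevel=2)
    return dataset.subset(keep)
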