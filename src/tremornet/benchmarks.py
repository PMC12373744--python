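"""Self-contained validation experiments for the whole pipeline.

Each function regenerates its inputs from the synthetic cohort machinery,
runs the analysis under test, and returns a scalar summary.  They back both
the acceptance test suite and the ``scripts/acceptance.py`` report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import classify as classify_mod
from .cascn import PseudoTimeSeries, roi_cascn_matrix, signed_path_gca, threshold_network
from .groupdiff import (
    cluster_correct_mcs,
    fit_vertex_glm,
    make_group_design,
    residual_maps,
    summary_stat_tests,
)
from .pipeline import demo_config, run_pipeline
from .scn import (
    estimate_smoothness,
    extract_seed,
    grf_cluster_correct,
    scn_interaction_map,
)
from .simulate import default_spec, simulate_cohort, simulate_null_cohort

RECOVERY_ROIS = (
    "TP.R", "PreCG.L", "PCUN.R", "EC.L", "MOF.R", "CUN.L", "SFG.R", "IPL.R",
)


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# 1. GCA oracle equivalence
# ---------------------------------------------------------------------------

def gca_oracle_max_error(n_series: int = 1000, length: int = 69, seed: int = 0) -> float:
    """Max |c_impl - c_oracle| over random series; the oracle is an
    independent least-squares solve of the lag design."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    ids = tuple(f"s{i}" for i in range(length))
    durations = np.arange(length, dtype=float)
    for _ in range(n_series):
        xv = rng.standard_normal(length)
        yv = rng.standard_normal(length)
        res = signed_path_gca(
            PseudoTimeSeries(ids, durations, xv),
            PseudoTimeSeries(ids, durations, yv),
        )
        X = np.column_stack([np.ones(length - 1), yv[:-1], xv[:-1]])
        coef, *_ = np.linalg.lstsq(X, yv[1:], rcond=None)
        worst = max(worst, abs(res.coefficient - coef[2]))
    return worst


# ---------------------------------------------------------------------------
# 2. planted-source recovery
# ---------------------------------------------------------------------------

def source_recovery_rate(n_runs: int = 50, seed: int = 0, z_threshold: float = 3.0) -> float:
    """Fraction of seeded cohorts in which the cascade source attains a
    strictly maximal binary out-degree (default single-source cascade,
    5-year lag, duration distribution of the larger patient group)."""
    spec = dataclasses.replace(default_spec(), n_td=2, n_et=70, n_hc=2)
    wins = 0
    for s in _spawn(seed, n_runs):
        ds = simulate_cohort(dataclasses.replace(spec, seed=s))
        net = threshold_network(
            roi_cascn_matrix(ds, "ET", RECOVERY_ROIS, weight_kind="t"), z_threshold
        )
        out = net.out_degree
        wins += out[0] > out[1:].max()
    return wins / n_runs


# ---------------------------------------------------------------------------
# 3. cluster-correction calibration
# ---------------------------------------------------------------------------

def cluster_calibration(
    n_runs: int = 200, n_iter: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Familywise error of MCS and GRF cluster correction on null cohorts
    (~1900-vertex grid atlas, two groups of 40)."""
    spec = dataclasses.replace(
        default_spec(), n_td=40, n_et=2, n_hc=40,
        n_regions=16, vertices_per_region=121, smoothing_fwhm=2.5,
    )
    mcs_fp = grf_fp = 0
    for s in _spawn(seed, n_runs):
        ds = simulate_null_cohort(dataclasses.replace(spec, seed=s))
        sub, design = make_group_design(ds, ("TD", "HC"))
        stat_map = fit_vertex_glm(sub, design)
        mcs = cluster_correct_mcs(stat_map, ds.atlas, n_iter=n_iter, seed=s)
        mcs_fp += len(mcs.significant) > 0
        smoothness = estimate_smoothness(residual_maps(sub, design), ds.atlas)
        grf = grf_cluster_correct(stat_map, ds.atlas, smoothness)
        grf_fp += len(grf.significant) > 0
    return mcs_fp / n_runs, grf_fp / n_runs


# ---------------------------------------------------------------------------
# 4. SCN interaction power
# ---------------------------------------------------------------------------

def scn_power(n_runs: int = 100, seed: int = 0, correlation: float = 0.7) -> float:
    """Detection rate of a planted seed-target covariance difference:
    HC seed-target correlation ``correlation`` vs 0 in patients, n=70/70."""
    spec = dataclasses.replace(
        default_spec(), n_td=70, n_et=2, n_hc=70,
        vertices_per_region=36, smoothing_fwhm=5.0,
    )
    seed_region, target_region = "PCUN.R", "MOF.R"
    hits = 0
    for s in _spawn(seed, n_runs):
        ds = simulate_null_cohort(dataclasses.replace(spec, seed=s))
        tgt = ds.atlas.vertices_of(target_region)
        hc = ds.group_mask("HC")
        sv = extract_seed(ds, seed_region).values
        zc = (sv - sv[hc].mean()) / sv[hc].std()
        tgt_mean_sd = ds.thickness[np.ix_(hc, tgt)].mean(axis=1).std()
        lam = tgt_mean_sd * correlation / np.sqrt(1.0 - correlation**2)
        ds.thickness[np.ix_(hc, tgt)] += lam * zc[hc][:, None]
        series = extract_seed(ds, seed_region)
        sub, stat_map = scn_interaction_map(ds, series, ("TD", "HC"))
        _, design = make_group_design(ds, ("TD", "HC"))
        smoothness = estimate_smoothness(residual_maps(sub, design), ds.atlas)
        result = grf_cluster_correct(stat_map, ds.atlas, smoothness)
        hits += any(
            np.intersect1d(c.vertices, tgt).size > 0 and c.peak_stat < 0
            for c in result.significant
        )
    return hits / n_runs


# ---------------------------------------------------------------------------
# 6. classifier sanity
# ---------------------------------------------------------------------------

def _gaussian_table(n_per_class: int, d_prime: float, rng, n_noise: int = 4):
    y = np.array(["TD"] * n_per_class + ["ET"] * n_per_class)
    X = pd.DataFrame({
        "signal": np.where(y == "TD", d_prime, 0.0) + rng.standard_normal(y.size),
        **{f"noise{i}": rng.standard_normal(y.size) for i in range(n_noise)},
    })
    return classify_mod.FeatureTable(X=X, labels=y)


def binormal_auc_gap(n_reps: int = 5, d_prime: float = 1.5, seed: int = 0) -> tuple[float, float]:
    """(mean bootstrap AUC of a linear SVM, closed-form binormal AUC) on
    two-Gaussian single-signal data."""
    rng = np.random.default_rng(seed)
    aucs = []
    for rep_seed in _spawn(seed, n_reps):
        table = _gaussian_table(200, d_prime, rng)
        train, test = classify_mod.split_train_test(table, seed=rep_seed)
        bundle = classify_mod.train_models(
            train, ["signal"], learners=("SVM-linear",), seed=rep_seed
        )
        evals = classify_mod.evaluate_resampled_auc(
            bundle, test, n_resamples=200, seed=rep_seed
        )
        aucs.append(evals["SVM-linear"].mean_auc)
    expected = float(norm.cdf(d_prime / np.sqrt(2.0)))
    return float(np.mean(aucs)), expected


def shuffled_label_null(
    n_repeats: int = 200, threshold: int = 100, seed: int = 0
) -> dict:
    """Shuffled-label controls: stability-selection count and test AUC."""
    rng = np.random.default_rng(seed)
    table = _gaussian_table(70, 1.5, rng, n_noise=9)
    shuffled = classify_mod.FeatureTable(
        X=table.X, labels=rng.permutation(table.labels)
    )
    train, test = classify_mod.split_train_test(shuffled, seed=seed)
    profile = classify_mod.lasso_stability_select(
        train, n_repeats=n_repeats, threshold=threshold, seed=seed
    )
    aucs = []
    for rep_seed in _spawn(seed + 1, 3):
        rng2 = np.random.default_rng(rep_seed)
        t2 = _gaussian_table(200, 1.5, rng2)
        sh2 = classify_mod.FeatureTable(X=t2.X, labels=rng2.permutation(t2.labels))
        tr2, te2 = classify_mod.split_train_test(sh2, seed=rep_seed)
        bundle = classify_mod.train_models(
            tr2, ["signal"], learners=("SVM-linear",), seed=rep_seed
        )
        evals = classify_mod.evaluate_resampled_auc(
            bundle, te2, n_resamples=200, seed=rep_seed
        )
        aucs.append(evals["SVM-linear"].mean_auc)
    return {
        "n_selected": len(profile.selected),
        "max_count": int(profile.counts.max()),
        "mean_auc": float(np.mean(aucs)),
    }


# ---------------------------------------------------------------------------
# 7. summary-statistic soft checks
# ---------------------------------------------------------------------------

#: printed cohort summaries (mean, sd, n) used as inputs
TABLE1_SUMMARIES = {
    "duration": {"TD": (9.28, 7.16, 69), "ET": (16.41, 12.48, 71)},
    "MoCA": {"TD": (23.36, 3.04, 69), "ET": (21.38, 4.88, 71)},
    "age": {"TD": (63.62, 6.66, 69), "ET": (65.31, 7.91, 71)},
}


def table1_welch() -> dict[str, float]:
    out = summary_stat_tests(TABLE1_SUMMARIES, "welch_t")
    return {var: float(out.loc[var, "p"]) for var in TABLE1_SUMMARIES}


# ---------------------------------------------------------------------------
# 8. end-to-end determinism
# ---------------------------------------------------------------------------

def demo_reproducibility(workdir, master_seed: int = 0) -> bool:
    """Run the scaled demo pipeline twice; True iff output hashes agree."""
    workdir = Path(workdir)
    hashes = []
    for tag in ("a", "b"):
        manifests = run_pipeline(demo_config(str(workdir / f"run_{tag}"), master_seed))
        digest = hashlib.sha256(
            json.dumps(
                {s: m["outputs"] for s, m in manifests.items()}, sort_keys=True
            ).encode()
        ).hexdigest()
        hashes.append(digest)
    return hashes[0] == hashes[1]
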