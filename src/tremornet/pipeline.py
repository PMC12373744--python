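"""End-to-end orchestration: config, seeding, manifests, report.

A single master seed deterministically derives one seed per stage via
``numpy.random.SeedSequence``; every stage writes its artifacts plus a
machine-readable manifest (parameters, seed, output hashes), so reruns with
the same config are hash-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cascn as cascn_mod
from . import classify as classify_mod
from . import groupdiff, io, scn as scn_mod
from .errors import ConfigurationError
from .simulate import CohortSpec, default_spec, simulate_cohort

log = logging.getLogger("tremornet")

STAGES = ("simulate", "group_diff", "scn", "cascn", "classify")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters; defaults follow the printed analysis settings
    (cluster-forming p 0.01, cluster-wise alpha 0.05, GRF alpha 0.05,
    causal-map cluster > 10 vertices, LASSO 1000 repeats / >500 threshold,
    3:1 split, 10-fold CV, 1000 resamples)."""

    outdir: str = "tremornet_out"
    master_seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort_spec: Optional[str] = None  # path to a cohort spec, else the default

    cluster_forming_p: float = 0.01
    cluster_alpha: float = 0.05
    mcs_iterations: int = 1000
    ancova_covariates: tuple[str, ...] = ("age", "sex")

    scn_seeds: tuple[str, ...] = ("PCUN.R", "MOF.R", "CUN.L")
    scn_alpha: float = 0.05
    scn_correction: str = "grf"

    cascn_group_seeds: tuple[tuple[str, str], ...] = (
        ("TD", "PCUN.R"), ("ET", "MOF.R"), ("ET", "CUN.L"),
    )
    cascn_order: int = 1
    cascn_min_cluster: int = 10
    cascn_permutations: int = 1000
    cascn_z_threshold: float = 1.0
    cascn_rois: tuple[str, ...] = ()  # empty: all atlas regions

    feature_set: str = "combined"
    selection_mode: str = "count_threshold"
    lasso_repeats: int = 1000
    lasso_threshold: int = 500
    cv_folds: int = 10
    auc_resamples: int = 1000

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("stages", "scn_seeds", "ancova_covariates", "cascn_rois"):
            if key in d:
                d[key] = tuple(d[key])
        if "cascn_group_seeds" in d:
            d["cascn_group_seeds"] = tuple(tuple(x) for x in d["cascn_group_seeds"])
        cfg = cls(**d)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ConfigurationError(f"unknown stages: {bad}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def demo_config(outdir: str, master_seed: int = 0) -> PipelineConfig:
    """Scaled-down configuration that completes in a couple of minutes on
    one CPU while exercising every stage."""
    return PipelineConfig(
        outdir=outdir,
        master_seed=master_seed,
        mcs_iterations=200,
        cascn_permutations=200,
        lasso_repeats=100,
        lasso_threshold=50,
        auc_resamples=200,
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, seed: int,
                    outputs: list[Path]) -> dict:
    manifest = {
        "stage": stage,
        "seed": int(seed),
        "params": params,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(outputs)},
    }
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("stage %s complete: %d outputs", stage, len(outputs))
    return manifest


def _stage_seeds(master_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0])
        for stage, child in zip(STAGES, children)
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns stage manifests."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed)
    log.info("stage seeds: %s", seeds)
    manifests: dict[str, dict] = {}

    spec = (
        CohortSpec.from_yaml(config.cohort_spec)
        if config.cohort_spec
        else default_spec()
    )
    spec = replace(spec, seed=seeds["simulate"])
    dataset = simulate_cohort(spec)

    if "simulate" in config.stages:
        paths = io.write_dataset(dataset, outdir / "cohort")
        spec_path = outdir / "cohort" / "cohort_spec.yaml"
        spec.to_yaml(spec_path)
        manifests["simulate"] = _write_manifest(
            outdir, "simulate", {"spec": spec.to_dict()}, seeds["simulate"],
            list(paths.values()) + [spec_path],
        )

    if "group_diff" in config.stages:
        manifests["group_diff"] = _run_group_diff(config, dataset, outdir, seeds["group_diff"])
    if "scn" in config.stages:
        manifests["scn"] = _run_scn(config, dataset, outdir, seeds["scn"])
    if "cascn" in config.stages:
        manifests["cascn"] = _run_cascn(config, dataset, outdir, seeds["cascn"])
    if "classify" in config.stages:
        manifests["classify"] = _run_classify(config, dataset, outdir, seeds["classify"])

    report_path = outdir / "report.md"
    report_path.write_text(make_report(manifests, outdir))
    return manifests


def _run_group_diff(config, dataset, outdir: Path, seed: int) -> dict:
    stage_dir = outdir / "group_diff"
    stage_dir.mkdir(exist_ok=True)
    outputs = []
    rng = np.random.default_rng(seed)
    for patient in ("TD", "ET"):
        sub, design = groupdiff.make_group_design(dataset, (patient, "HC"))
        stat_map = groupdiff.fit_vertex_glm(sub, design)
        result = groupdiff.cluster_correct_mcs(
            stat_map, dataset.atlas,
            cluster_forming_p=config.cluster_forming_p,
            alpha=config.cluster_alpha,
            n_iter=config.mcs_iterations,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        path = stage_dir / f"clusters_{patient}_vs_HC.csv"
        result.to_frame().to_csv(path, index=False)
        outputs.append(path)
    posthoc = groupdiff.subcortical_ancova(
        dataset, covariates=config.ancova_covariates, alpha=config.cluster_alpha
    )
    path = stage_dir / "subcortical_ancova.csv"
    posthoc.to_frame().to_csv(path)
    outputs.append(path)
    params = {
        "cluster_forming_p": config.cluster_forming_p,
        "alpha": config.cluster_alpha,
        "n_iter": config.mcs_iterations,
        "covariates": list(config.ancova_covariates),
    }
    return _write_manifest(outdir, "group_diff", params, seed, outputs)


def _run_scn(config, dataset, outdir: Path, seed: int) -> dict:
    stage_dir = outdir / "scn"
    stage_dir.mkdir(exist_ok=True)
    outputs = []
    rng = np.random.default_rng(seed)
    for seed_region in config.scn_seeds:
        for patient in ("TD", "ET"):
            series = scn_mod.extract_seed(dataset, seed_region)
            sub, stat_map = scn_mod.scn_interaction_map(
                dataset, series, (patient, "HC")
            )
            _, gdesign = groupdiff.make_group_design(dataset, (patient, "HC"))
            resid = groupdiff.residual_maps(sub, gdesign)
            smoothness = scn_mod.estimate_smoothness(resid, dataset.atlas)
            result = scn_mod.grf_cluster_correct(
                stat_map, dataset.atlas, smoothness,
                cluster_forming_p=config.cluster_forming_p,
                alpha=config.scn_alpha,
                method=config.scn_correction,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            path = stage_dir / f"scn_{seed_region.replace('.', '_')}_{patient}.csv"
            result.to_frame().to_csv(path, index=False)
            outputs.append(path)
            scatter = pd.DataFrame({
                "seed_mean": series.values[dataset.group_mask(patient, "HC")],
                "group": sub.groups,
            })
            spath = stage_dir / f"scatter_{seed_region.replace('.', '_')}_{patient}.csv"
            scatter.to_csv(spath, index=False)
            outputs.append(spath)
    params = {"seeds": list(config.scn_seeds), "alpha": config.scn_alpha,
              "correction": config.scn_correction}
    return _write_manifest(outdir, "scn", params, seed, outputs)


def _run_cascn(config, dataset, outdir: Path, seed: int) -> dict:
    stage_dir = outdir / "cascn"
    stage_dir.mkdir(exist_ok=True)
    outputs = []
    rng = np.random.default_rng(seed)
    for group, seed_region in config.cascn_group_seeds:
        stat_map, clusters = cascn_mod.vertexwise_cascn(
            dataset, group, seed_region,
            order=config.cascn_order,
            min_cluster=config.cascn_min_cluster,
            n_perm=config.cascn_permutations,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        tag = f"{group}_{seed_region.replace('.', '_')}"
        path = stage_dir / f"cascn_clusters_{tag}.csv"
        clusters.to_frame().to_csv(path, index=False)
        outputs.append(path)
        zpath = stage_dir / f"cascn_zmap_{tag}.csv"
        pd.DataFrame({"z": stat_map.statistic, "corrected_p": stat_map.p}).to_csv(
            zpath, index_label="vertex")
        outputs.append(zpath)
    for group in ("TD", "ET"):
        rois = list(config.cascn_rois) or list(dataset.atlas.region_names)
        network = cascn_mod.roi_cascn_matrix(
            dataset, group, rois, order=config.cascn_order
        )
        network = cascn_mod.threshold_network(network, config.cascn_z_threshold)
        mpath = stage_dir / f"gc_matrix_{group}.csv"
        pd.DataFrame(network.weights, index=rois, columns=rois).to_csv(mpath)
        outputs.append(mpath)
        gpath = stage_dir / f"network_{group}.graphml"
        io.write_network(network, gpath, "graphml")
        outputs.append(gpath)
        dpath = stage_dir / f"degrees_{group}.csv"
        network.degree_table().to_csv(dpath)
        outputs.append(dpath)
    params = {
        "group_seeds": [list(x) for x in config.cascn_group_seeds],
        "order": config.cascn_order,
        "min_cluster": config.cascn_min_cluster,
        "n_perm": config.cascn_permutations,
        "z_threshold": config.cascn_z_threshold,
    }
    return _write_manifest(outdir, "cascn", params, seed, outputs)


def _run_classify(config, dataset, outdir: Path, seed: int) -> dict:
    stage_dir = outdir / "classify"
    stage_dir.mkdir(exist_ok=True)
    outputs = []
    rng = np.random.default_rng(seed)
    table = classify_mod.build_feature_table(dataset, config.feature_set)
    train, test = classify_mod.split_train_test(
        table, seed=int(rng.integers(0, 2**31 - 1))
    )
    train, test = classify_mod.impute_train_test(train, test)
    profile = classify_mod.lasso_stability_select(
        train,
        n_repeats=config.lasso_repeats,
        cv_folds=config.cv_folds,
        threshold=config.lasso_threshold,
        mode=config.selection_mode,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ppath = stage_dir / "selection_profile.csv"
    profile.to_frame().to_csv(ppath, index_label="feature")
    outputs.append(ppath)
    selected = profile.selected or list(profile.counts.index[:3])
    bundle = classify_mod.train_models(
        train, selected, inner_cv=config.cv_folds,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    evals = classify_mod.evaluate_resampled_auc(
        bundle, test, n_resamples=config.auc_resamples,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    apath = stage_dir / "auc_table.csv"
    classify_mod.evaluation_table(evals).to_csv(apath)
    outputs.append(apath)
    params = {
        "feature_set": config.feature_set,
        "selection_mode": config.selection_mode,
        "lasso_repeats": config.lasso_repeats,
        "lasso_threshold": config.lasso_threshold,
        "cv_folds": config.cv_folds,
        "auc_resamples": config.auc_resamples,
        "selected": selected,
    }
    return _write_manifest(outdir, "classify", params, seed, outputs)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def make_report(manifests: dict, outdir) -> str:
    """Deterministic markdown summary; every number traces to a manifest."""
    outdir = Path(outdir)
    lines = ["# tremornet run report", ""]
    if not manifests:
        lines.append("_No manifests supplied._")
        return "\n".join(lines) + "\n"
    for stage in STAGES:
        lines.append(f"## {stage}")
        manifest = manifests.get(stage)
        if manifest is None:
            lines.append("_absent_")
            lines.append("")
            continue
        lines.append(f"- seed: `{manifest['seed']}`")
        for key, value in sorted(manifest["params"].items()):
            if key == "spec":
                continue
            lines.append(f"- {key}: `{value}`")
        for rel in manifest["outputs"]:
            path = outdir / rel
            if path.suffix == ".csv" and path.exists():
                table = pd.read_csv(path)
                lines.append("")
                lines.append(f"### {rel} ({len(table)} rows)")
                lines.append("```")
                lines.append(table.head(12).to_string(index=False))
                lines.append("```")
        lines.append("")
    return "\n".join(lines) + "\n"
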