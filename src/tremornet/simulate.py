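"""Synthetic cohort generation.

Cohorts carry the statistical structure the downstream analyses assume:
spatially smooth thickness noise on a grid atlas, duration-dependent
cascading regional effects for patients, group-shifted subcortical volumes,
and group-shifted clinical covariates.  Everything is reproducible from the
spec's single seed.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import SCORE_NAMES, MorphometryDataset, SubjectMetadata, SurfaceAtlas
from .errors import ConfigurationError
from .fields import smooth_fields, smoothing_gain


@dataclass(frozen=True)
class CascadeEdge:
    """One duration-lagged propagation edge between two regions.

    The source region's planted deviation for a patient with duration ``d``
    is ``effect_rate * min(d, saturation)``; the target's is
    ``effect_rate * min(max(d - lag, 0), saturation)``.
    """

    source: str
    target: str
    effect_rate: float  # mm per year
    lag: float  # years
    saturation: float  # years

    def __post_init__(self):
        if self.lag < 0:
            raise ConfigurationError(f"cascade lag must be >= 0, got {self.lag}")
        if self.saturation <= 0:
            raise ConfigurationError(
                f"cascade saturation must be > 0, got {self.saturation}"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort (serializable as YAML)."""

    n_td: int = 69
    n_et: int = 71
    n_hc: int = 80
    n_regions: int = 16
    vertices_per_region: int = 36
    baseline_mean: float = 2.5  # mm
    noise_sd: float = 0.25  # mm, after smoothing
    smoothing_fwhm: float = 5.0  # vertex units
    duration_dist: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"TD": (9.28, 7.16), "ET": (16.41, 12.48)}
    )
    cascade: tuple[CascadeEdge, ...] = ()
    subcortical_baselines: Mapping[str, float] = field(
        default_factory=lambda: {
            "Pallidum.L": 1898.06,
            "Pallidum.R": 1865.46,
            "Thalamus.L": 7004.12,
            "Thalamus.R": 7003.37,
        }
    )
    subcortical_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "Pallidum.L": 231.29,
            "Pallidum.R": 257.89,
            "Thalamus.L": 699.08,
            "Thalamus.R": 648.91,
        }
    )
    subcortical_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    clinical_means: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    age_dist: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "TD": (63.62, 6.66),
            "ET": (65.31, 7.91),
            "HC": (63.84, 5.16),
        }
    )
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"TD": 32 / 69, "ET": 39 / 71, "HC": 43 / 80}
    )
    education_dist: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "TD": (14.13, 10.51),
            "ET": (13.61, 4.66),
            "HC": (12.98, 5.30),
        }
    )
    hy_stage_probs: tuple[float, ...] = (0.10, 0.19, 0.50, 0.21)  # stages 1..4
    region_names: Optional[tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self):
        for name, n in (("n_td", self.n_td), ("n_et", self.n_et), ("n_hc", self.n_hc)):
            if n < 2:
                raise ConfigurationError(f"{name} must be >= 2, got {n}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_td": self.n_td,
            "n_et": self.n_et,
            "n_hc": self.n_hc,
            "n_regions": self.n_regions,
            "vertices_per_region": self.vertices_per_region,
            "baseline_mean": self.baseline_mean,
            "noise_sd": self.noise_sd,
            "smoothing_fwhm": self.smoothing_fwhm,
            "duration_dist": {g: list(v) for g, v in self.duration_dist.items()},
            "cascade": [
                {
                    "source": e.source,
                    "target": e.target,
                    "effect_rate": e.effect_rate,
                    "lag": e.lag,
                    "saturation": e.saturation,
                }
                for e in self.cascade
            ],
            "subcortical_baselines": dict(self.subcortical_baselines),
            "subcortical_noise_sd": dict(self.subcortical_noise_sd),
            "subcortical_effects": {
                s: dict(g) for s, g in self.subcortical_effects.items()
            },
            "clinical_means": {
                g: {k: list(v) for k, v in m.items()}
                for g, m in self.clinical_means.items()
            },
            "age_dist": {g: list(v) for g, v in self.age_dist.items()},
            "female_fraction": dict(self.female_fraction),
            "education_dist": {g: list(v) for g, v in self.education_dist.items()},
            "hy_stage_probs": list(self.hy_stage_probs),
            "region_names": list(self.region_names) if self.region_names else None,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown cohort-spec keys: {sorted(unknown)}")
        if "cascade" in d:
            d["cascade"] = tuple(
                e if isinstance(e, CascadeEdge) else CascadeEdge(**e)
                for e in d["cascade"]
            )
        for key in ("duration_dist", "age_dist", "education_dist"):
            if key in d:
                d[key] = {g: tuple(v) for g, v in d[key].items()}
        if "clinical_means" in d:
            d["clinical_means"] = {
                g: {k: tuple(v) for k, v in m.items()}
                for g, m in d["clinical_means"].items()
            }
        if "hy_stage_probs" in d:
            d["hy_stage_probs"] = tuple(d["hy_stage_probs"])
        if d.get("region_names"):
            d["region_names"] = tuple(d["region_names"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_spec(seed: int = 0) -> CohortSpec:
    """The shipped paper-shaped cohort spec (``table1_like.cfg``)."""
    ref = importlib.resources.files("tremornet").joinpath("data/table1_like.cfg")
    with importlib.resources.as_file(ref) as path:
        spec = CohortSpec.from_yaml(path)
    return replace(spec, seed=seed)


# ---------------------------------------------------------------------------
# atlas construction
# ---------------------------------------------------------------------------

def _balanced_factors(n: int) -> tuple[int, int]:
    a = int(math.isqrt(n))
    while n % a:
        a -= 1
    return a, n // a


def make_atlas(
    n_regions: int,
    vertices_per_region: int,
    seed: int = 0,
    region_names: Optional[Sequence[str]] = None,
) -> SurfaceAtlas:
    """Grid-graph atlas partitioned into equal rectangular regions.

    Regions are laid out as a grid of blocks so each is connected.  The
    construction is fully deterministic; ``seed`` is accepted for interface
    symmetry with the simulators but does not influence the layout.
    """
    if n_regions < 2:
        raise ConfigurationError(f"need at least 2 regions, got {n_regions}")
    if vertices_per_region < 4:
        raise ConfigurationError(
            f"regions need >= 4 vertices for clusters, got {vertices_per_region}"
        )
    br, bc = _balanced_factors(n_regions)  # block layout
    vr, vc = _balanced_factors(vertices_per_region)  # vertices per block
    h, w = br * vr, bc * vc
    idx = np.arange(h * w).reshape(h, w)

    # 4-connected lattice edges
    horiz = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1)
    vert = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1)
    edges = np.concatenate([horiz, vert], axis=0)

    region_of_vertex = (np.arange(h)[:, None] // vr) * bc + (np.arange(w)[None, :] // vc)
    if region_names is None:
        region_names = [f"R{i:02d}" for i in range(n_regions)]
    elif len(region_names) != n_regions:
        raise ConfigurationError(
            f"{len(region_names)} region names for {n_regions} regions"
        )
    return SurfaceAtlas(
        edges=edges,
        region_of_vertex=region_of_vertex.ravel(),
        region_names=region_names,
        grid_shape=(h, w),
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _truncnorm_at_zero(rng, mean, sd, size):
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def cascade_effect(spec: CohortSpec, atlas: SurfaceAtlas, durations: np.ndarray) -> np.ndarray:
    """Planted mean thickness deviation per (subject, vertex) for patients."""
    effect = np.zeros((durations.size, atlas.n_vertices))
    d = np.nan_to_num(durations, nan=0.0)[:, None]
    for edge in spec.cascade:
        src = atlas.vertices_of(edge.source)
        tgt = atlas.vertices_of(edge.target)
        effect[:, src] += edge.effect_rate * np.minimum(d, edge.saturation)
        effect[:, tgt] += edge.effect_rate * np.minimum(
            np.maximum(d - edge.lag, 0.0), edge.saturation
        )
    return effect


def simulate_cohort(spec: CohortSpec, atlas: Optional[SurfaceAtlas] = None) -> MorphometryDataset:
    """Draw one cohort according to ``spec`` (deterministic per seed)."""
    if atlas is None:
        atlas = make_atlas(
            spec.n_regions, spec.vertices_per_region, region_names=spec.region_names
        )
    for edge in spec.cascade:
        for name in (edge.source, edge.target):
            if name not in atlas.region_names:
                raise ConfigurationError(f"cascade names unknown region {name!r}")
    rng = np.random.default_rng(spec.seed)

    groups = ["TD"] * spec.n_td + ["ET"] * spec.n_et + ["HC"] * spec.n_hc
    n = len(groups)
    subjects: list[SubjectMetadata] = []
    durations = np.full(n, np.nan)
    for i, g in enumerate(groups):
        sid = f"S{i + 1:04d}"
        age = float(rng.normal(*spec.age_dist[g]))
        sex = "F" if rng.random() < spec.female_fraction[g] else "M"
        edu = float(max(0.0, rng.normal(*spec.education_dist[g])))
        duration = None
        hy = None
        if g in spec.duration_dist:
            mean, sd = spec.duration_dist[g]
            duration = float(_truncnorm_at_zero(rng, mean, sd, 1)[0])
            durations[i] = duration
        if g == "TD":
            probs = np.asarray(spec.hy_stage_probs, dtype=float)
            hy = int(rng.choice(np.arange(1, probs.size + 1), p=probs / probs.sum()))
        scores = {}
        for name in SCORE_NAMES:
            dist = spec.clinical_means.get(g, {}).get(name)
            scores[name] = None if dist is None else float(rng.normal(*dist))
        subjects.append(
            SubjectMetadata(
                subject_id=sid, group=g, age=age, sex=sex, education=edu,
                duration=duration, hy_stage=hy, scores=scores,
            )
        )

    # thickness: smooth noise scaled to the requested field sd, plus effects
    white = rng.standard_normal((n, atlas.n_vertices))
    gain = smoothing_gain(atlas, spec.smoothing_fwhm)
    noise = smooth_fields(white, atlas, spec.smoothing_fwhm) * (spec.noise_sd / gain)
    thickness = spec.baseline_mean + noise
    is_patient = np.array([g != "HC" for g in groups])
    if spec.cascade:
        effect = cascade_effect(spec, atlas, durations)
        thickness[is_patient] += effect[is_patient]

    # subcortical volumes
    vol_cols = {}
    for struct, base in spec.subcortical_baselines.items():
        sd = spec.subcortical_noise_sd.get(struct, 0.1 * base)
        shift = np.array(
            [spec.subcortical_effects.get(struct, {}).get(g, 0.0) for g in groups]
        )
        vol_cols[struct] = base + shift + rng.normal(0.0, sd, size=n)
    volumes = pd.DataFrame(vol_cols, index=pd.Index([s.subject_id for s in subjects],
                                                    name="subject_id"))
    return MorphometryDataset(
        atlas=atlas, thickness=thickness, volumes=volumes, subjects=subjects
    )


def simulate_null_cohort(spec: CohortSpec, atlas: Optional[SurfaceAtlas] = None) -> MorphometryDataset:
    """Same draw machinery with every planted effect forced to zero.

    Groups, durations and clinical covariates are still drawn, so group
    labels are exchangeable with respect to thickness and volumes.
    """
    null_spec = replace(spec, cascade=(), subcortical_effects={})
    return simulate_cohort(null_spec, atlas=atlas)
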