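import dataclasses

import numpy as np
import pandas as pd
import pytest

import tremornet as tn
from tremornet.core import SubjectMetadata


@pytest.fixture(scope="session")
def small_atlas():
    return tn.make_atlas(4, 25, seed=0)


@pytest.fixture(scope="session")
def small_spec():
    """Fast cohort: 16 subjects per patient group, 256-vertex atlas."""
    spec = tn.default_spec(seed=11)
    return dataclasses.replace(
        spec, n_td=16, n_et=16, n_hc=16, vertices_per_region=16, smoothing_fwhm=2.0
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return tn.simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def null_cohort(small_spec):
    return tn.simulate_null_cohort(small_spec)


def make_manual_dataset(values_by_group, atlas=None, volumes_shift=None):
    """Tiny hand-built dataset: one thickness value per subject broadcast to
    all vertices unless per-vertex rows are supplied."""
    if atlas is None:
        atlas = tn.make_atlas(2, 4, seed=0)
    rows, subjects = [], []
    i = 0
    for group, values in values_by_group.items():
        for v in values:
            i += 1
            sid = f"{group}{i:03d}"
            row = np.full(atlas.n_vertices, float(v)) if np.isscalar(v) else np.asarray(v, float)
            rows.append(row)
            subjects.append(
                SubjectMetadata(
                    subject_id=sid, group=group, age=60.0 + i, sex="M" if i % 2 else "F",
                    education=12.0, duration=None if group == "HC" else 5.0 + i,
                    hy_stage=2 if group == "TD" else None,
                )
            )
    ids = [s.subject_id for s in subjects]
    jitter = np.arange(len(ids)) % 4  # balanced across equal-sized groups
    vols = pd.DataFrame(
        {
            "Pallidum.L": 1900.0 + jitter,
            "Pallidum.R": 1870.0 + jitter,
            "Thalamus.L": 7000.0 + jitter,
            "Thalamus.R": 7000.0 + jitter,
        },
        index=pd.Index(ids, name="subject_id"),
    )
    if volumes_shift:
        for col, shifts in volumes_shift.items():
            vols[col] = vols[col] + shifts
    return tn.MorphometryDataset(
        atlas=atlas, thickness=np.array(rows), volumes=vols, subjects=subjects
    )
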