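import dataclasses

import numpy as np
import pytest

import tremornet as tn
from tremornet import scn
from tremornet.errors import DegenerateDataError, NamingError, UsageError
from tremornet.fields import estimate_fwhm, smooth_fields
from tremornet.groupdiff import make_group_design, residual_maps

from conftest import make_manual_dataset


class TestExtractSeed:
    def test_constant_region(self):
        ds = make_manual_dataset({"TD": [2.5, 2.5], "HC": [2.5, 2.5]})
        series = scn.extract_seed(ds, ds.atlas.region_names[0])
        np.testing.assert_array_equal(series.values, 2.5)

    def test_two_vertex_mean(self):
        atlas = tn.make_atlas(2, 4)
        row = np.zeros(atlas.n_vertices) + 2.0
        row[atlas.vertices_of(atlas.region_names[0])[:2]] = [2.0, 3.0]
        row[atlas.vertices_of(atlas.region_names[0])[2:]] = [2.0, 3.0]
        ds = make_manual_dataset({"TD": [row], "HC": [2.5]}, atlas=atlas)
        series = scn.extract_seed(ds, atlas.region_names[0])
        assert series.values[0] == pytest.approx(2.5)

    def test_unknown_region(self, small_cohort):
        with pytest.raises(NamingError, match="PCUN.X"):
            scn.extract_seed(small_cohort, "PCUN.X")


def interaction_oracle(y, s, g, covs=()):
    """Brute-force normal equations for the seed-x-group coefficient t."""
    s_c = s - s.mean()
    X = np.column_stack([np.ones(len(y)), s_c, g, s_c * g, *covs])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    return beta[3] / np.sqrt(sigma2 * xtx_inv[3, 3])


class TestInteractionMap:
    def _toy(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        atlas = tn.make_atlas(2, 4)
        rows = list(rng.normal(2.5, 0.3, size=(2 * n, atlas.n_vertices)))
        return make_manual_dataset(
            {"TD": rows[:n], "HC": rows[n:]}, atlas=atlas
        )

    def test_matches_normal_equations_oracle(self):
        ds = self._toy()
        region = ds.atlas.region_names[0]
        series = scn.extract_seed(ds, region)
        sub, stat_map = scn.scn_interaction_map(
            ds, series, ("TD", "HC"), covariates=()
        )
        g = (sub.groups == "TD").astype(float)
        target_vertices = ds.atlas.vertices_of(ds.atlas.region_names[1])
        for v in target_vertices:
            expected = interaction_oracle(sub.thickness[:, v], series.values, g)
            assert stat_map.statistic[v] == pytest.approx(expected, abs=1e-10)

    def test_8_subject_hand_listed(self):
        atlas = tn.make_atlas(2, 4)
        seed_vals = np.array([1.0, 1.2, 1.4, 1.6, 1.1, 1.3, 1.5, 1.7]) + 1.0
        target_vals = np.array([2.0, 2.5, 2.9, 3.4, 3.1, 2.9, 2.7, 2.5])
        rows = []
        for sv, tv in zip(seed_vals, target_vals):
            row = np.empty(atlas.n_vertices)
            row[atlas.vertices_of(atlas.region_names[0])] = sv
            row[atlas.vertices_of(atlas.region_names[1])] = tv
            rows.append(row)
        ds = make_manual_dataset({"TD": rows[:4], "HC": rows[4:]}, atlas=atlas)
        series = scn.extract_seed(ds, atlas.region_names[0])
        _, stat_map = scn.scn_interaction_map(ds, series, ("TD", "HC"), covariates=())
        g = np.array([1.0] * 4 + [0.0] * 4)
        v = atlas.vertices_of(atlas.region_names[1])[0]
        expected = interaction_oracle(target_vals, seed_vals, g)
        assert stat_map.statistic[v] == pytest.approx(expected, abs=1e-10)

    def test_coding_symmetry(self):
        ds = self._toy(seed=3)
        region = ds.atlas.region_names[0]
        series = scn.extract_seed(ds, region)
        _, forward = scn.scn_interaction_map(ds, series, ("TD", "HC"), covariates=())
        _, swapped = scn.scn_interaction_map(ds, series, ("HC", "TD"), covariates=())
        np.testing.assert_allclose(forward.statistic, -swapped.statistic, atol=1e-10)

    def test_seed_region_excluded(self):
        ds = self._toy(seed=5)
        region = ds.atlas.region_names[0]
        series = scn.extract_seed(ds, region)
        _, stat_map = scn.scn_interaction_map(ds, series, ("TD", "HC"), covariates=())
        own = ds.atlas.vertices_of(region)
        np.testing.assert_array_equal(stat_map.statistic[own], 0.0)
        np.testing.assert_array_equal(stat_map.p[own], 1.0)

    def test_constant_seed_rejected(self):
        ds = make_manual_dataset({"TD": [2.5, 2.5, 2.5], "HC": [2.4, 2.5, 2.6]})
        series = scn.extract_seed(ds, ds.atlas.region_names[0])
        with pytest.raises(DegenerateDataError):
            scn.scn_interaction_map(ds, series, ("TD", "HC"), covariates=())

    def test_foreign_seed_rejected(self, small_cohort):
        ds = self._toy()
        series = scn.extract_seed(small_cohort, "PCUN.R")
        with pytest.raises(UsageError):
            scn.scn_interaction_map(ds, series, ("TD", "HC"))


class TestSmoothnessEstimate:
    def test_white_noise_resolves_to_one_vertex(self):
        atlas = tn.make_atlas(16, 64)
        rng = np.random.default_rng(0)
        maps = rng.standard_normal((20, atlas.n_vertices))
        est = scn.estimate_smoothness(maps, atlas)
        assert est.fwhm == pytest.approx(1.0, abs=0.3)

    def test_recovers_known_kernel_within_20pct(self):
        atlas = tn.make_atlas(16, 64)
        rng = np.random.default_rng(1)
        maps = smooth_fields(rng.standard_normal((20, atlas.n_vertices)), atlas, 5.0)
        est = scn.estimate_smoothness(maps, atlas)
        assert abs(est.fwhm - 5.0) / 5.0 < 0.20
        assert est.resels == pytest.approx(atlas.n_vertices / est.fwhm**2)

    def test_constant_maps_rejected(self, small_atlas):
        with pytest.raises(DegenerateDataError):
            scn.estimate_smoothness(np.ones((3, small_atlas.n_vertices)), small_atlas)

    def test_single_map_rejected(self, small_atlas):
        with pytest.raises(UsageError):
            scn.estimate_smoothness(np.zeros((1, small_atlas.n_vertices)), small_atlas)


class TestGRFCorrection:
    def test_no_suprathreshold_empty(self, small_atlas):
        n = small_atlas.n_vertices
        stat_map = tn.StatMap(statistic=np.zeros(n), p=np.ones(n), df=50.0)
        sm = scn.SmoothnessEstimate(fwhm=3.0, resels=n / 9.0)
        result = scn.grf_cluster_correct(stat_map, small_atlas, sm)
        assert result.clusters == []

    def test_lenient_threshold_warns(self, small_atlas):
        n = small_atlas.n_vertices
        stat_map = tn.StatMap(statistic=np.zeros(n), p=np.ones(n), df=50.0)
        sm = scn.SmoothnessEstimate(fwhm=3.0, resels=n / 9.0)
        with pytest.warns(UserWarning, match="approximation"):
            scn.grf_cluster_correct(stat_map, small_atlas, sm, cluster_forming_p=0.05)

    def test_planted_interaction_survives(self):
        spec = dataclasses.replace(
            tn.default_spec(seed=21), n_td=60, n_et=2, n_hc=60,
            vertices_per_region=36, smoothing_fwhm=5.0, cascade=(),
        )
        ds = tn.simulate_cohort(spec)
        tgt = ds.atlas.vertices_of("MOF.R")
        hc = ds.group_mask("HC")
        sv = scn.extract_seed(ds, "PCUN.R").values
        zc = (sv - sv[hc].mean()) / sv[hc].std()
        lam = ds.thickness[np.ix_(hc, tgt)].mean(axis=1).std()
        ds.thickness[np.ix_(hc, tgt)] += lam * zc[hc][:, None]
        series = scn.extract_seed(ds, "PCUN.R")
        sub, stat_map = scn.scn_interaction_map(ds, series, ("TD", "HC"))
        _, design = make_group_design(ds, ("TD", "HC"))
        sm = scn.estimate_smoothness(residual_maps(sub, design), ds.atlas)
        result = scn.grf_cluster_correct(stat_map, ds.atlas, sm)
        hit = [c for c in result.significant if np.intersect1d(c.vertices, tgt).size]
        assert hit and hit[0].peak_stat < 0

    def test_permutation_fallback_runs(self, null_cohort):
        sub, design = make_group_design(null_cohort, ("TD", "HC"))
        stat_map = tn.fit_vertex_glm(sub, design)
        sm = scn.estimate_smoothness(residual_maps(sub, design), null_cohort.atlas)
        result = scn.grf_cluster_correct(
            stat_map, null_cohort.atlas, sm, method="permutation", n_iter=100, seed=0
        )
        assert result.method == "mcs"


class TestCorrelationDifferenceCrossCheck:
    def test_agrees_in_sign_with_interaction(self):
        rng = np.random.default_rng(9)
        atlas = tn.make_atlas(2, 4)
        n = 40
        seed_vals = rng.normal(0, 1, 2 * n)
        target = np.where(np.arange(2 * n) >= n, seed_vals, 0.0) * 0.2
        rows = []
        for i in range(2 * n):
            row = np.full(atlas.n_vertices, 2.5)
            row[atlas.vertices_of(atlas.region_names[0])] = 2.5 + 0.2 * seed_vals[i]
            row[atlas.vertices_of(atlas.region_names[1])] = (
                2.5 + target[i] + 0.05 * rng.standard_normal()
            )
            rows.append(row)
        ds = make_manual_dataset({"TD": rows[:n], "HC": rows[n:]}, atlas=atlas)
        series = scn.extract_seed(ds, atlas.region_names[0])
        _, imap = scn.scn_interaction_map(ds, series, ("TD", "HC"), covariates=())
        zmap = scn.scn_correlation_difference(ds, series, ("TD", "HC"))
        v = atlas.vertices_of(atlas.region_names[1])
        assert imap.statistic[v].mean() < 0
        assert zmap.statistic[v].mean() < 0
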