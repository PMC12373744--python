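import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tremornet as tn
from tremornet import groupdiff
from tremornet.errors import ConfigurationError, DesignError, UsageError, ValidationError

from conftest import make_manual_dataset


def two_sample_t_oracle(a, b):
    """Closed-form pooled two-sample t, independent of the GLM path."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


class TestFitVertexGLM:
    def test_matches_two_sample_t_oracle(self):
        a, b = [2.6, 2.7, 2.8], [2.1, 2.2, 2.3]
        ds = make_manual_dataset({"TD": a, "HC": b})
        sub, design = groupdiff.make_group_design(ds, ("TD", "HC"), covariates=())
        stat_map = groupdiff.fit_vertex_glm(sub, design)
        expected = two_sample_t_oracle(a, b)
        np.testing.assert_allclose(stat_map.statistic, expected, atol=1e-10)
        assert stat_map.df == 4

    def test_random_data_matches_oracle_everywhere(self):
        rng = np.random.default_rng(0)
        atlas = tn.make_atlas(2, 4)
        td = rng.normal(2.5, 0.2, size=(9, atlas.n_vertices))
        hc = rng.normal(2.5, 0.2, size=(12, atlas.n_vertices))
        ds = make_manual_dataset(
            {"TD": list(td), "HC": list(hc)}, atlas=atlas
        )
        sub, design = groupdiff.make_group_design(ds, ("TD", "HC"), covariates=())
        stat_map = groupdiff.fit_vertex_glm(sub, design)
        for v in range(atlas.n_vertices):
            assert stat_map.statistic[v] == pytest.approx(
                two_sample_t_oracle(td[:, v], hc[:, v]), abs=1e-10
            )

    def test_null_t_near_zero(self, null_cohort):
        sub, design = groupdiff.make_group_design(null_cohort, ("TD", "HC"))
        stat_map = groupdiff.fit_vertex_glm(sub, design)
        assert abs(stat_map.statistic.mean()) < 0.5

    def test_orthogonal_covariate_leaves_group_t_close(self):
        rng = np.random.default_rng(1)
        atlas = tn.make_atlas(2, 4)
        td = rng.normal(2.5, 0.2, size=(10, atlas.n_vertices))
        hc = rng.normal(2.5, 0.2, size=(10, atlas.n_vertices))
        ds = make_manual_dataset({"TD": list(td), "HC": list(hc)}, atlas=atlas)
        _, d0 = groupdiff.make_group_design(ds, ("TD", "HC"), covariates=())
        # covariate exactly orthogonal to intercept and group indicator
        cov = np.tile([1.0, -1.0], 10)
        X = np.column_stack([d0.matrix, cov])
        d1 = groupdiff.DesignMatrix(X, d0.columns + ["orth"], np.append(d0.contrast, 0.0))
        t0 = groupdiff.fit_vertex_glm(ds, d0).statistic
        t1 = groupdiff.fit_vertex_glm(ds, d1).statistic
        np.testing.assert_allclose(t0, t1, atol=0.15)  # identical up to df change

    def test_rank_deficiency_names_columns(self, null_cohort):
        sub, design = groupdiff.make_group_design(null_cohort, ("TD", "HC"))
        X = np.column_stack([design.matrix, design.matrix[:, 1]])
        bad = groupdiff.DesignMatrix(
            X, design.columns + ["dup"], np.append(design.contrast, 0.0)
        )
        with pytest.raises(DesignError, match="dup"):
            groupdiff.fit_vertex_glm(sub, bad)


class TestClusterCorrectMCS:
    def test_planted_effect_recovered_at_floor(self, null_cohort):
        ds = null_cohort
        region = ds.atlas.vertices_of("PCUN.R")
        thick = ds.thickness.copy()
        sd = thick.std()
        thick[np.ix_(ds.group_mask("TD"), region)] += 6.0 * sd
        planted = tn.MorphometryDataset(ds.atlas, thick, ds.volumes, ds.subjects)
        sub, design = groupdiff.make_group_design(planted, ("TD", "HC"))
        stat_map = groupdiff.fit_vertex_glm(sub, design)
        result = groupdiff.cluster_correct_mcs(stat_map, ds.atlas, n_iter=199, seed=0)
        assert result.significant
        top = result.significant[0]
        assert top.corrected_p == pytest.approx(1.0 / 200.0)
        assert set(region) <= set(top.vertices)

    def test_no_suprathreshold_returns_empty(self, small_atlas):
        n = small_atlas.n_vertices
        stat_map = tn.StatMap(statistic=np.zeros(n), p=np.ones(n), df=20.0)
        result = groupdiff.cluster_correct_mcs(stat_map, small_atlas, n_iter=100, seed=0)
        assert result.clusters == []

    def test_low_n_iter_rejected(self, small_atlas):
        n = small_atlas.n_vertices
        stat_map = tn.StatMap(statistic=np.zeros(n), p=np.ones(n), df=20.0)
        with pytest.raises(ConfigurationError):
            groupdiff.cluster_correct_mcs(stat_map, small_atlas, n_iter=50, seed=0)


class TestSubcorticalAncova:
    def test_identical_groups_no_discoveries(self):
        ds = make_manual_dataset({"TD": [2.5] * 4, "ET": [2.5] * 4, "HC": [2.5] * 4})
        table = groupdiff.subcortical_ancova(ds, covariates=()).to_frame()
        assert (table["p_fdr"] >= 0.05).all()

    def test_unknown_structure_named(self, small_cohort):
        with pytest.raises(tn.errors.NamingError, match="Putamen.L"):
            groupdiff.subcortical_ancova(small_cohort, structures=["Putamen.L"])

    def test_posthoc_bonferroni_triples_p(self):
        spec = dataclasses.replace(tn.default_spec(seed=8), vertices_per_region=16)
        ds = tn.simulate_cohort(spec)
        result = groupdiff.subcortical_ancova(ds)
        table = result.to_frame()
        assert (table["p_fdr"] >= table["p_raw"] - 1e-15).all()
        sig = table[table["p_fdr"] < 0.05]
        assert len(sig) > 0
        for col in ("p_TD_ET", "p_TD_HC", "p_ET_HC"):
            assert (sig[col] <= 1.0).all()

    def test_missing_group_rejected(self):
        ds = make_manual_dataset({"TD": [2.5, 2.6, 2.4], "HC": [2.5, 2.6, 2.4]})
        with pytest.raises(UsageError, match="three groups"):
            groupdiff.subcortical_ancova(ds)


class TestBHAdjust:
    def test_hand_applied_step_up(self):
        p = np.array([0.001, 0.02, 0.03, 0.4])
        np.testing.assert_allclose(
            groupdiff.bh_adjust(p), [0.004, 0.04, 0.04, 0.4], atol=1e-12
        )

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=30)
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_order_invariant(self, p_list):
        p = np.array(p_list)
        adj = groupdiff.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(groupdiff.bh_adjust(p[perm]), adj[perm], atol=1e-12)


class TestSummaryStatTests:
    def test_duration_welch_below_printed_bound(self):
        rows = {"duration": {"TD": (9.28, 7.16, 69), "ET": (16.41, 12.48, 71)}}
        out = groupdiff.summary_stat_tests(rows, "welch_t")
        assert out.loc["duration", "p"] < 0.001

    def test_identical_summaries_give_t_zero(self):
        rows = {"x": {"a": (5.0, 1.0, 20), "b": (5.0, 1.0, 20)}}
        out = groupdiff.summary_stat_tests(rows, "student_t")
        assert out.loc["x", "statistic"] == 0.0
        assert out.loc["x", "p"] == pytest.approx(1.0)

    def test_moca_welch_matches_closed_form_oracle(self):
        m1, s1, n1 = 23.36, 3.04, 69
        m2, s2, n2 = 21.38, 4.88, 71
        t_oracle = (m1 - m2) / math.sqrt(s1**2 / n1 + s2**2 / n2)
        out = groupdiff.summary_stat_tests(
            {"MoCA": {"TD": (m1, s1, n1), "ET": (m2, s2, n2)}}, "welch_t"
        )
        assert out.loc["MoCA", "statistic"] == pytest.approx(t_oracle, abs=1e-10)
        assert t_oracle == pytest.approx(2.89, abs=0.02)

    def test_three_group_anova(self):
        rows = {"age": {"TD": (63.62, 6.66, 69), "ET": (65.31, 7.91, 71),
                        "HC": (63.84, 5.16, 80)}}
        out = groupdiff.summary_stat_tests(rows, "oneway_anova")
        assert out.loc["age", "p"] > 0.05

    def test_bad_arity(self):
        with pytest.raises(UsageError, match="exactly 2"):
            groupdiff.summary_stat_tests(
                {"x": {"a": (1, 1, 5), "b": (1, 1, 5), "c": (1, 1, 5)}}, "welch_t"
            )


class TestForwardInferenceBinomial:
    def test_exact_tail_sum_oracle(self):
        k, n, q = 9, 10, 0.2
        expected = sum(
            math.comb(n, i) * q**i * (1 - q) ** (n - i) for i in range(k, n + 1)
        )
        out = groupdiff.forward_inference_binomial({"motor": (k, n)}, base_rate=q)
        assert out.loc["motor", "p"] == pytest.approx(expected, rel=1e-12)

    def test_k_zero_gives_p_one(self):
        out = groupdiff.forward_inference_binomial({"d": (0, 50)}, base_rate=0.2)
        assert out.loc["d", "p"] == pytest.approx(1.0)

    def test_boundary_near_half(self):
        out = groupdiff.forward_inference_binomial({"d": (200, 1000)}, base_rate=0.2)
        assert 0.4 < out.loc["d", "p"] < 0.6

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValidationError):
            groupdiff.forward_inference_binomial({"d": (11, 10)}, base_rate=0.2)


class TestEarlyStageFilter:
    def test_td_hy_rule(self, small_cohort):
        sub = groupdiff.early_stage_filter(small_cohort, "td_hy_le2")
        groups = sub.groups
        assert (groups == "ET").sum() == 0
        for s in sub.subjects:
            if s.group == "TD":
                assert s.hy_stage <= 2
        assert (groups == "HC").sum() == (small_cohort.groups == "HC").sum()

    def test_et_duration_strictly_below_10(self):
        ds = make_manual_dataset({"ET": [2.5, 2.6], "HC": [2.5, 2.4, 2.3]})
        ds.subjects[0].duration = 9.9
        ds.subjects[1].duration = 10.0
        sub = groupdiff.early_stage_filter(ds, "et_duration_lt10")
        kept = [s.duration for s in sub.subjects if s.group == "ET"]
        assert kept == [9.9]

    def test_empty_result_warns_not_crashes(self):
        ds = make_manual_dataset({"ET": [2.5, 2.6], "HC": [2.5, 2.4]})
        for s in ds.subjects:
            if s.group == "ET":
                s.duration = 20.0
        with pytest.warns(UserWarning, match="retained no patients"):
            sub = groupdiff.early_stage_filter(ds, "et_duration_lt10")
        assert (sub.groups == "ET").sum() == 0

    def test_unknown_rule(self, small_cohort):
        with pytest.raises(UsageError):
            groupdiff.early_stage_filter(small_cohort, "hc_only")
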