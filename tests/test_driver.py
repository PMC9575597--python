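"""End-to-end study orchestration."""

import math

import numpy as np
import pandas as pd
import pytest

from subshape import scenarios as sc
from subshape.cohort import CohortConfig, simulate_cohort
from subshape.driver import (
    ContrastSpec,
    StudyData,
    run_clinical_regression,
    run_contrast,
    run_moderator,
    summarize_clusters,
)
from subshape.fdr import SignificanceMap, bh_reject, build_neighborhoods
from subshape.glm import fit_site_glm
from subshape.meta import MetaStats
from subshape.simulate import EffectSpec, simulate_shape_maps


@pytest.fixture(scope="module")
def data(atlas, cohort):
    maps = simulate_shape_maps(atlas, cohort, (sc.POWER_MATCHED_DEP,), seed=77)
    return StudyData(atlas, cohort, maps)


class TestRunContrast:
    def test_detects_power_matched_cluster(self, data, neighborhoods):
        res = run_contrast(data, sc.CONTRAST_DEP_VS_CONTROLS, neighborhoods=neighborhoods)
        rows = res.clusters.query(
            "structure == 'pallidum' and hemisphere == 'R' and measure == 'logj'"
        )
        assert len(rows) >= 1
        assert rows.peak_d.abs().max() > 0.2

    def test_deterministic_output(self, atlas, cohort, neighborhoods):
        frames = []
        for _ in range(2):
            maps = simulate_shape_maps(atlas, cohort, (sc.POWER_MATCHED_DEP,), seed=77)
            res = run_contrast(
                StudyData(atlas, cohort, maps), sc.CONTRAST_DEP_VS_CONTROLS, neighborhoods=neighborhoods
            )
            frames.append(res.clusters.to_csv(index=None))
        assert frames[0] == frames[1]

    def test_overlapping_selectors_rejected(self, data):
        spec = ContrastSpec(name="bad", group_a="dx == 1", group_b="dx >= 0")
        with pytest.raises(ValueError, match="overlap"):
            run_contrast(data, spec)

    def test_no_eligible_site_raises(self, data):
        spec = ContrastSpec(name="empty", group_a="dx == 1 and age > 200", group_b="dx == 0")
        with pytest.raises(ValueError, match="no eligible site"):
            run_contrast(data, spec)

    def test_underpowered_site_excluded_exactly(self, atlas, neighborhoods):
        # a site with zero patients under the selector drops out, and the
        # result equals the meta-analysis over the remaining sites
        cfg = CohortConfig(
            sites=("a", "b", "c"),
            patients_per_site=(30, 30, 0),
            controls_per_site=(30, 30, 30),
            n_medicated=0,
            n_depression=30,
            n_anxiety=0,
            missing_clinical=0,
            missing_depression=0,
            missing_anxiety=0,
            missing_medication=0,
        )
        cohort = simulate_cohort(cfg, seed=4)
        maps = simulate_shape_maps(atlas, cohort, (), seed=5)
        res = run_contrast(
            StudyData(atlas, cohort, maps), ContrastSpec(name="main"), neighborhoods=neighborhoods
        )
        assert res.sites_used == ["a", "b"]
        assert "c" in res.sites_excluded
        kept = cohort[cohort.site != "c"].reset_index(drop=True)
        kept_rows = maps.rows_for(kept.subject_id)
        sub_maps_measures = {m: arr[kept_rows] for m, arr in maps.measures.items()}
        from subshape.maps import ShapeMaps

        sub_maps = ShapeMaps(list(kept.subject_id), sub_maps_measures, maps.structure_slices)
        res2 = run_contrast(
            StudyData(atlas, kept, sub_maps), ContrastSpec(name="main"), neighborhoods=neighborhoods
        )
        np.testing.assert_allclose(res.meta["logj"].d, res2.meta["logj"].d, atol=1e-12)

    def test_single_site_infinite_ladder_reduces_to_glm_plus_bh(self, atlas):
        # oracle equivalence: one site, ladder {inf} -> per-structure BH on
        # the GLM p-values converted through the normal pooled z
        cfg = CohortConfig(
            sites=("only",),
            patients_per_site=(60,),
            controls_per_site=(60,),
            n_medicated=0,
            n_depression=0,
            n_anxiety=0,
            missing_clinical=0,
            missing_depression=0,
            missing_anxiety=0,
            missing_medication=0,
        )
        cohort = simulate_cohort(cfg, seed=9)
        eff = EffectSpec(
            structure="pallidum",
            hemisphere="R",
            measure="logj",
            cluster_center=113,
            cluster_radius=5.0,
            d=1.2,
            pct=25.0,
        )
        maps = simulate_shape_maps(atlas, cohort, (eff,), seed=10)
        nb = build_neighborhoods(atlas, (math.inf,))
        res = run_contrast(
            StudyData(atlas, cohort, maps),
            ContrastSpec(name="main"),
            ladder=(math.inf,),
            neighborhoods=nb,
        )
        ms = res.meta["logj"]
        from scipy import stats as st

        g = (cohort.dx == 1).to_numpy().astype(float)
        site = fit_site_glm(maps.measures["logj"], cohort, g, measure="logj")
        # single-site pooling: d and its large-sample variance pass through
        np.testing.assert_allclose(ms.d, site.d, atol=1e-12)
        v = site.d_variance
        p = np.clip(2 * st.norm.sf(np.abs(site.d / np.sqrt(v))), np.finfo(float).tiny, 1)
        for mesh in atlas.structures:
            sl = atlas.slices[mesh.key]
            np.testing.assert_array_equal(
                res.sig["logj"].significant[sl], bh_reject(p[sl], 0.05)
            )


class TestModerators:
    def test_null_interactions_stay_null(self, data, neighborhoods):
        res = run_moderator(data, neighborhoods=neighborhoods)
        for term in ("age_x_group", "age2_x_group"):
            n_sig = sum(
                res.moderator_sig[term][m].significant.sum() for m in ("thickness", "logj")
            )
            assert n_sig <= 5   # no injected interaction: essentially empty maps

    def test_age_centering_leaves_main_effect_unchanged(self, data):
        res_plain = run_contrast(data, ContrastSpec(name="main"))
        shifted = data.cohort.copy()
        shifted["age"] = shifted["age"] - 31.0
        res_shift = run_contrast(
            StudyData(data.atlas, shifted, data.maps), ContrastSpec(name="main")
        )
        np.testing.assert_allclose(
            res_plain.meta["logj"].d, res_shift.meta["logj"].d, atol=1e-9
        )

    def test_injected_interaction_detected(self, atlas, neighborhoods):
        # build a strong age-by-group interaction by hand and check the
        # pooled interaction betas recover it
        cfg = CohortConfig(
            n_medicated=0, n_depression=0, n_anxiety=0,
            missing_clinical=0, missing_depression=0, missing_anxiety=0, missing_medication=0,
        )
        cohort = simulate_cohort(cfg, seed=12)
        maps = simulate_shape_maps(atlas, cohort, (), seed=13)
        cols = sc.DEP_SURFACE_PALLIDUM.vertices(atlas)
        slope = 0.05
        cage = cohort.age - cohort.groupby("site").age.transform("mean")
        bump = slope * (cage * (cohort.dx == 1)).to_numpy()
        maps.measures["logj"][:, cols] += bump[:, None]
        res = run_moderator(StudyData(atlas, cohort, maps), neighborhoods=neighborhoods)
        ms = res.moderator_meta["age_x_group"]["logj"]
        assert np.allclose(ms.beta[cols].mean(), slope, atol=0.01)
        assert res.moderator_sig["age_x_group"]["logj"].significant[cols].mean() > 0.9


class TestClinicalRegression:
    def test_recovers_injected_severity_association(self, atlas, cohort, neighborhoods):
        maps = simulate_shape_maps(atlas, cohort, (), seed=21)
        cols = sc.DEP_SURFACE_PALLIDUM.vertices(atlas)
        slope = 0.02   # logJ per Y-BOCS point: strong association
        y = cohort.ybocs_total.fillna(0).to_numpy()
        maps.measures["logj"][:, cols] += slope * (y - 25.0)[:, None] * (
            cohort.dx == 1
        ).to_numpy()[:, None]
        res = run_clinical_regression(
            StudyData(atlas, cohort, maps), "ybocs_total", neighborhoods=neighborhoods
        )
        assert res.meta["logj"].beta[cols].mean() == pytest.approx(slope, rel=0.2)
        assert res.sig["logj"].significant[cols].mean() > 0.9

    def test_null_association_stays_null(self, atlas, cohort, neighborhoods):
        maps = simulate_shape_maps(atlas, cohort, (), seed=22)
        res = run_clinical_regression(
            StudyData(atlas, cohort, maps), "duration", neighborhoods=neighborhoods
        )
        assert res.clusters.empty or res.clusters.n_vertices.sum() <= 5

    def test_constant_variable_excludes_site(self, atlas, neighborhoods):
        cfg = CohortConfig(
            sites=("a", "b"),
            patients_per_site=(30, 30),
            controls_per_site=(30, 30),
            n_medicated=0, n_depression=0, n_anxiety=0,
            missing_clinical=0, missing_depression=0, missing_anxiety=0, missing_medication=0,
        )
        cohort = simulate_cohort(cfg, seed=30)
        cohort.loc[(cohort.site == "b") & (cohort.dx == 1), "ybocs_total"] = 25.0
        maps = simulate_shape_maps(atlas, cohort, (), seed=31)
        res = run_clinical_regression(
            StudyData(atlas, cohort, maps), "ybocs_total", neighborhoods=neighborhoods
        )
        assert res.sites_used == ["a"]
        assert "b" in res.sites_excluded


class TestSummarizeClusters:
    def _empty_sig(self, atlas):
        V = atlas.total_vertex_count
        return SignificanceMap(
            significant=np.zeros(V, dtype=bool),
            radius=np.full(V, np.nan),
            q=0.05,
            k=np.full(V, 6),
            structure_slices=dict(atlas.slices),
        )

    def _meta(self, atlas, d):
        V = atlas.total_vertex_count
        return MetaStats(
            measure="logj",
            d=d,
            d_se=np.full(V, 0.1),
            beta=d * 0.1,
            beta_se=np.full(V, 0.02),
            tau2=np.zeros(V),
            Q=np.zeros(V),
            k=np.full(V, 6),
            z=d / 0.1,
            p=np.full(V, 0.5),
            control_mean=np.full(V, 2.0),
        )

    def test_empty_map_empty_table(self, atlas):
        sig = self._empty_sig(atlas)
        table = summarize_clusters(sig, self._meta(atlas, np.zeros(atlas.total_vertex_count)), atlas, "c", "logj")
        assert table.empty

    def test_single_cluster_row(self, atlas):
        sig = self._empty_sig(atlas)
        sl = atlas.slices[("pallidum", "R")]
        d = np.zeros(atlas.total_vertex_count)
        members = np.arange(sl.start + 100, sl.start + 110)
        sig.significant[members] = True
        sig.radius[members] = 4.0
        d[members] = 0.25
        d[members[3]] = 0.30
        table = summarize_clusters(sig, self._meta(atlas, d), atlas, "c", "logj")
        assert len(table) == 1
        row = table.iloc[0]
        assert row.n_vertices == 10
        assert row.peak_d == pytest.approx(0.30)
        assert row.min_radius == 4.0

    def test_rows_sorted_by_structure_then_hemisphere(self, atlas):
        sig = self._empty_sig(atlas)
        d = np.zeros(atlas.total_vertex_count)
        for key in [("putamen", "L"), ("caudate", "R"), ("caudate", "L")]:
            sl = atlas.slices[key]
            sig.significant[sl.start + 50] = True
            sig.radius[sl.start + 50] = 2.0
            d[sl.start + 50] = 0.2
        table = summarize_clusters(sig, self._meta(atlas, d), atlas, "c", "logj")
        assert list(zip(table.structure, table.hemisphere)) == [
            ("caudate", "L"),
            ("caudate", "R"),
            ("putamen", "L"),
        ]
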