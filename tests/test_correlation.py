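import numpy as np
import pytest

from optotract.config import RunConfig
from optotract.correlation import (
    SubjectData,
    TractHistologyModel,
    VoxelMask,
    connectivity_report,
    correlated_area,
    local_correlation,
    optimize_params,
)
from optotract.histology import fluorescence_to_surface
from optotract.synthetic import (
    TractGroundTruth,
    make_histology_block,
    make_labeled_surface,
    make_tractogram,
    region_origin_map,
)
from optotract.tracts import SeedSphere, SurfaceMap


def random_map(surface, rng, kind="density"):
    return SurfaceMap(values=rng.random(surface.n_vertices), kind=kind)


class TestLocalCorrelation:
    def test_identity_map_gives_r_one(self, folded_surface):
        rng = np.random.default_rng(0)
        m = random_map(folded_surface, rng)
        res = local_correlation(m, m, folded_surface, 3.0)
        assert res.defined.all()
        assert np.allclose(res.r_map.values, 1.0)

    def test_anti_identity_gives_r_minus_one(self, folded_surface):
        rng = np.random.default_rng(1)
        m = random_map(folded_surface, rng)
        neg = SurfaceMap(values=-m.values + 5.0, kind="correlation")
        res = local_correlation(m, neg, folded_surface, 3.0)
        assert np.allclose(res.r_map.values[res.defined], -1.0)

    def test_matches_brute_force_pearson_oracle(self, folded_surface):
        """Per-vertex r equals the direct Pearson formula on independently
        recomputed geodesic neighborhoods, to 1e-10."""
        from scipy.sparse.csgraph import dijkstra

        rng = np.random.default_rng(2)
        a = random_map(folded_surface, rng)
        b = random_map(folded_surface, rng)
        radius = 3.0
        res = local_correlation(a, b, folded_surface, radius)
        dist = dijkstra(folded_surface.edge_graph(), directed=False)
        for v in rng.choice(folded_surface.n_vertices, 120, replace=False):
            nbr = np.flatnonzero(dist[v] <= radius)
            av, bv = a.values[nbr], b.values[nbr]
            expect = np.corrcoef(av, bv)[0, 1]
            assert res.r_map.values[v] == pytest.approx(expect, abs=1e-10)

    def test_symmetric_in_map_arguments(self, folded_surface):
        rng = np.random.default_rng(3)
        a, b = random_map(folded_surface, rng), random_map(folded_surface, rng)
        r_ab = local_correlation(a, b, folded_surface, 2.0)
        r_ba = local_correlation(b, a, folded_surface, 2.0)
        assert np.array_equal(r_ab.defined, r_ba.defined)
        assert np.allclose(
            r_ab.r_map.values[r_ab.defined], r_ba.r_map.values[r_ba.defined]
        )

    def test_constant_neighborhoods_are_undefined(self, folded_surface):
        const = SurfaceMap(
            values=np.ones(folded_surface.n_vertices), kind="density"
        )
        rng = np.random.default_rng(4)
        res = local_correlation(
            const, random_map(folded_surface, rng), folded_surface, 3.0
        )
        assert not res.defined.any()


class TestCorrelatedArea:
    def test_r_one_everywhere_gives_region_area(self, folded_surface):
        rng = np.random.default_rng(5)
        m = random_map(folded_surface, rng)
        res = local_correlation(m, m, folded_surface, 3.0)
        area = correlated_area(res, 1, 0.5)
        assert area == pytest.approx(folded_surface.region_area(1))

    def test_alternating_r_keeps_about_half_the_region(self, sheet):
        res = local_correlation(
            SurfaceMap(np.ones(sheet.n_vertices), "density"),
            SurfaceMap(np.ones(sheet.n_vertices), "density"),
            sheet, 2.0,
        )
        # overwrite with a constructed alternating map
        res.defined[:] = True
        res.r_map.values[:] = np.where(
            np.arange(sheet.n_vertices) % 2 == 0, 0.6, 0.4
        )
        area = correlated_area(res, 1, 0.5)
        kept = np.arange(sheet.n_vertices) % 2 == 0
        assert area == pytest.approx(sheet.vertex_areas[kept].sum())
        assert abs(area - sheet.total_area / 2) <= sheet.vertex_areas.max() * (
            sheet.n_vertices / 2
        ) * 0.5 + sheet.vertex_areas.max()

    def test_all_undefined_gives_zero(self, folded_surface):
        const = SurfaceMap(np.ones(folded_surface.n_vertices), "density")
        res = local_correlation(const, const, folded_surface, 3.0)
        assert correlated_area(res, 1, 0.5) == 0.0

    def test_monotone_non_increasing_in_threshold(self, folded_surface):
        rng = np.random.default_rng(6)
        res = local_correlation(
            random_map(folded_surface, rng), random_map(folded_surface, rng),
            folded_surface, 3.0,
        )
        areas = [correlated_area(res, 1, th) for th in (-0.5, 0.0, 0.3, 0.6)]
        assert all(x >= y for x, y in zip(areas, areas[1:]))

    def test_unknown_region_raises(self, folded_surface):
        rng = np.random.default_rng(7)
        m = random_map(folded_surface, rng)
        res = local_correlation(m, m, folded_surface, 2.0)
        with pytest.raises(KeyError):
            correlated_area(res, 99, 0.5)


def build_subject(surface, omap, tract_seed, histo_seed, truth=None):
    truth = truth or TractGroundTruth()
    tg, _ = make_tractogram(surface, truth, rng_seed=tract_seed)
    block = make_histology_block(surface, omap, rng_seed=histo_seed)
    hmap = fluorescence_to_surface(block, surface, 3.0)
    return SubjectData(
        surface=surface, histology_map=hmap, tractogram=tg,
        sphere=SeedSphere(np.asarray(truth.seed_center_mm), 1.0),
    )


class TestOptimizeParams:
    def test_single_cell_grid_returns_that_cell(self, folded_surface):
        omap = region_origin_map(folded_surface, 1)
        subj = build_subject(folded_surface, omap, 0, 0)
        best, table = optimize_params([subj], ([2.0], [30.0]), 1)
        assert (best.depth_mm, best.angle_deg) == (2.0, 30.0)
        assert len(table) == 1

    def test_two_subject_parameter_recovery(self):
        surfaces = [make_labeled_surface(3, 20, s) for s in (31, 32)]
        subjects = [
            build_subject(s, region_origin_map(s, 1), 100 + i, 200 + i)
            for i, s in enumerate(surfaces)
        ]
        cfg = RunConfig()
        best, _ = optimize_params(
            subjects, (cfg.grid_depths_mm, cfg.grid_angles_deg), 1, cfg
        )
        assert (best.depth_mm, best.angle_deg) == (2.0, 30.0)

    def test_degenerate_objective_returns_tie_break_cell(self, folded_surface):
        # histology map with no variance: correlation undefined -> zero areas
        flat = SurfaceMap(np.ones(folded_surface.n_vertices), "fluorescence")
        truth = TractGroundTruth(n_true=5, n_decoy=0)
        tg, _ = make_tractogram(folded_surface, truth, rng_seed=0)
        subj = SubjectData(
            surface=folded_surface, histology_map=flat, tractogram=tg,
            sphere=SeedSphere(np.asarray(truth.seed_center_mm), 1.0),
        )
        best, table = optimize_params([subj], ([2.0, 3.0], [0.0, 30.0]), 1)
        assert best.mean_area_mm2 == 0.0
        assert (best.depth_mm, best.angle_deg) == (2.0, 0.0)


class TestConnectivityReport:
    def test_planted_region_split_recovered(self, config):
        surf = make_labeled_surface(3, 20, 55)
        tractograms = []
        params = []
        from optotract.correlation import OptimalParams
        from optotract.tracts import Tractogram

        counts = {1: 25, 2: 15, 3: 10}
        streamlines = []
        for region, n in counts.items():
            truth = TractGroundTruth(n_true=n, n_decoy=0, origin_region=region)
            tg, _ = make_tractogram(surf, truth, rng_seed=region)
            streamlines.extend(tg.streamlines)
            params.append(OptimalParams(region, 2.0, 30.0, 1.0))
        tractogram = Tractogram(streamlines)
        report = connectivity_report(
            tractogram,
            SeedSphere(np.array([15.0, 15.0, -15.0]), 1.0),
            surf, params, config,
        )
        t = report.table.set_index("region")
        assert t.loc[1, "pct_fibers_mean"] == pytest.approx(50.0)
        assert t.loc[2, "pct_fibers_mean"] == pytest.approx(30.0)
        assert t.loc[3, "pct_fibers_mean"] == pytest.approx(20.0)
        assert t["pct_fibers_mean"].sum() == pytest.approx(100.0)

    def test_terminals_everywhere_give_full_surface_fraction(self, config):
        from optotract.correlation import _surface_projection_fraction

        surf = make_labeled_surface(2, 15, 0)
        idx = surf.region_vertices(1)
        frac = _surface_projection_fraction(surf, 1, idx, config.density_smoothing_mm)
        assert frac == pytest.approx(100.0)

    def test_voxel_mask_target_selection(self, config):
        surf = make_labeled_surface(2, 15, 1)
        truth = TractGroundTruth(n_true=10, n_decoy=6)
        tg, ann = make_tractogram(surf, truth, rng_seed=0)
        mask = VoxelMask(
            data=np.ones((4, 4, 4), dtype=bool),
            origin_mm=np.asarray(truth.seed_center_mm) - 1.0,
            voxel_size_mm=0.5,
        )
        from optotract.correlation import OptimalParams

        report = connectivity_report(
            tg, mask, surf, [OptimalParams(1, 2.0, 30.0, 1.0)], config
        )
        # decoys missing the seed sphere also miss the 2 mm mask cube
        n_kept = report.per_hemisphere["n_fibers"].sum()
        assert n_kept == truth.n_true


def test_model_fit_summary_reports_optimal_cells():
    surf = make_labeled_surface(2, 18, 77)
    omap = region_origin_map(surf, 1)
    subj = build_subject(surf, omap, 5, 6)
    cfg = RunConfig(grid_depths_mm=(2.0,), grid_angles_deg=(0.0, 30.0))
    results = TractHistologyModel([subj], cfg).fit(regions=[1])
    assert results.params_by_region[0].region == 1
    assert results.params_by_region[0].angle_deg == 30.0
    assert "depth" in results.summary()
    assert len(results.params_frame) == 1
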