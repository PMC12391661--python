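import numpy as np
import pytest

import porehull as ph


def _cube_pore(scale=1.0, tid="cube"):
    pts = scale * np.array(
        [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)], float
    )
    tr = ph.Track(tid, np.arange(8.0), pts)
    ts = ph.TrackSet(tracks=[tr], bead_diameter=1.0, dims=3)
    return ph.build_pore_models(ts, min_track_length=2).models[0]


class TestVolumeSampling:
    def test_all_selected_when_budget_not_binding(self):
        pores = [_cube_pore(2.0, i) for i in range(4)]  # 8 um^3 each
        sel, total = ph.sample_pores_by_volume(pores, ph.SamplingPolicy(volume_budget=1000.0))
        assert len(sel) == 4
        assert total == pytest.approx(32.0)

    def test_greedy_stop_before_overflow(self):
        # 100000 um^3 pores against the default 300000 budget: exactly 3 fit
        import dataclasses

        pores = [dataclasses.replace(_cube_pore(2.0, i), volume=100_000.0)
                 for i in range(10)]
        sel, total = ph.sample_pores_by_volume(pores, ph.SamplingPolicy())
        assert len(sel) == 3
        assert total == pytest.approx(300_000.0)

    def test_same_seed_same_selection(self):
        rng = np.random.default_rng(0)
        pores = [_cube_pore(float(s), i) for i, s in enumerate(rng.uniform(1, 40, 30))]
        policy = ph.SamplingPolicy(volume_budget=50_000.0, seed=5)
        sel1, _ = ph.sample_pores_by_volume(pores, policy)
        sel2, _ = ph.sample_pores_by_volume(pores, policy)
        assert [p.track_id for p in sel1] == [p.track_id for p in sel2]

    def test_empty_input_gives_empty_output(self):
        assert ph.sample_pores_by_volume([], ph.SamplingPolicy()) == ([], 0.0)

    def test_selection_always_within_budget(self):
        rng = np.random.default_rng(1)
        pores = [_cube_pore(float(s), i) for i, s in enumerate(rng.uniform(1, 30, 50))]
        for seed in range(10):
            _, total = ph.sample_pores_by_volume(
                pores, ph.SamplingPolicy(volume_budget=10_000.0, seed=seed)
            )
            assert total <= 10_000.0


class TestFlattening:
    def test_cube_projects_to_unit_square(self):
        flat = ph.flatten_pore(_cube_pore())
        assert flat.area == pytest.approx(1.0)
        assert flat.diameter_2d == pytest.approx(np.sqrt(2.0))
        assert flat.centroid == pytest.approx((0.5, 0.5))

    def test_octahedron_projects_to_square_of_area_two(self):
        pts = np.array([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                        (0, 0, 1), (0, 0, -1)], float)
        tr = ph.Track("oct", np.arange(6.0), pts)
        ts = ph.TrackSet(tracks=[tr], bead_diameter=1.0, dims=3)
        pore = ph.build_pore_models(ts, min_track_length=2).models[0]
        flat = ph.flatten_pore(pore)
        assert flat.area == pytest.approx(2.0)
        assert flat.centroid == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_flattening_never_increases_feret(self, sphere18_models):
        flats = ph.flatten_pores(sphere18_models)
        for m, f in zip(sphere18_models, flats):
            assert f.diameter_2d <= m.diameter_raw + 1e-9

    def test_median_2d_diameter_underestimates_3d_corrected(self, sphere18_models):
        flats = ph.flatten_pores(sphere18_models)
        med2d = np.median([f.diameter_2d for f in flats])
        med3d = np.median([m.diameter_corrected for m in sphere18_models])
        assert med2d < med3d

    def test_ring_is_closed(self, sphere18_models):
        f = ph.flatten_pore(sphere18_models[0])
        assert np.array_equal(f.vertices_2d[0], f.vertices_2d[-1])


class TestResolutionFilter:
    def _flat(self, diameter, area, tid=0):
        ring = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        return ph.FlatPore(tid, ring, area=area, diameter_2d=diameter, centroid=(0.5, 0.5))

    def test_small_area_pore_removed(self):
        res = ph.apply_resolution_filter(
            [self._flat(5.0, 9.0)], ph.SamplingPolicy(min_area=10.0)
        )
        assert res.kept == []
        assert res.removed_by_area == 1

    def test_zero_thresholds_are_identity(self):
        flats = [self._flat(1.0, 1.0, i) for i in range(3)]
        res = ph.apply_resolution_filter(
            flats, ph.SamplingPolicy(min_diameter=0.0, min_area=0.0)
        )
        assert [f.source_track_id for f in res.kept] == [0, 1, 2]

    def test_all_below_threshold_removed_with_counts(self):
        flats = [self._flat(0.5, 100.0, 0), self._flat(50.0, 1.0, 1)]
        res = ph.apply_resolution_filter(
            flats, ph.SamplingPolicy(min_diameter=1.0, min_area=10.0)
        )
        assert res.kept == []
        assert res.removed_by_diameter == 1
        assert res.removed_by_area == 1

    def test_filter_is_idempotent(self):
        rng = np.random.default_rng(2)
        flats = [self._flat(d, a, i)
                 for i, (d, a) in enumerate(zip(rng.uniform(0, 30, 40),
                                                rng.uniform(0, 40, 40)))]
        policy = ph.SamplingPolicy(min_diameter=5.0, min_area=10.0)
        once = ph.apply_resolution_filter(flats, policy)
        twice = ph.apply_resolution_filter(once.kept, policy)
        assert all(a is b for a, b in zip(twice.kept, once.kept))
        assert len(twice.kept) == len(once.kept)
        assert twice.removed_by_diameter == twice.removed_by_area == 0


class TestDistributionComparison:
    def test_identical_samples_maximal_p(self):
        res = ph.compare_distributions([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_gives_zero_U(self):
        res = ph.compare_distributions([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert res.statistic == 0.0
        assert res.median_a == 2.0
        assert res.median_b == 102.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ph.TrackValidationError):
            ph.compare_distributions([], [1.0])

    def test_null_p_values_are_uniform(self):
        # two draws from one distribution: p should be uniform over repeats
        rng = np.random.default_rng(3)
        pvals = [
            ph.compare_distributions(rng.normal(10, 2, 30), rng.normal(10, 2, 30)).p_value
            for _ in range(500)
        ]
        from scipy import stats

        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_bonferroni_caps_at_one(self):
        assert ph.bonferroni([0.01, 0.5]) == [0.02, 1.0]
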