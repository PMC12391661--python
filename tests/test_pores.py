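import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import porehull as ph
from conftest import brute_force_hull_2d, brute_force_hull_3d


def _track(points, tid=1):
    pts = np.asarray(points, float)
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    return ph.Track(tid, np.arange(len(pts), dtype=float), pts)


class TestHullConstruction:
    def test_unit_tetrahedron_volume(self):
        hull = ph.hull_from_track(
            _track([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]), dims=3
        )
        assert hull.volume == pytest.approx(1.0 / 6.0)

    def test_unit_cube_volume_and_surface(self):
        corners = [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
        hull = ph.hull_from_track(_track(corners), dims=3)
        assert hull.volume == pytest.approx(1.0)
        assert hull.surface_area == pytest.approx(6.0)

    def test_sphere_cloud_volume_converges_from_below(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(10_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = 5.0 * rng.random(10_000)[:, None] ** (1 / 3) * v
        hull = ph.hull_from_track(_track(pts), dims=3)
        target = 4.0 / 3.0 * np.pi * 125.0
        assert hull.volume < target
        assert hull.volume == pytest.approx(target, rel=0.05)

    def test_coplanar_3d_cloud_raises_degeneracy_naming_track(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0) ** 2, np.zeros(5)])
        with pytest.raises(ph.DegenerateGeometryError, match="flat"):
            ph.hull_from_track(_track(pts, tid="flat"), dims=3)

    def test_too_few_points_raises_validation(self):
        with pytest.raises(ph.TrackValidationError):
            ph.hull_from_track(_track([(0, 0, 0), (1, 0, 0), (0, 1, 0)]), dims=3)

    def test_2d_ring_is_closed_ccw_from_lowest_vertex(self):
        hull = ph.hull_from_track(_track([(0, 1), (1, 0), (1, 1), (0, 0), (0.5, 0.5)]), dims=2)
        ring = hull.vertices
        assert np.array_equal(ring[0], ring[-1])
        assert np.array_equal(ring[0], [0.0, 0.0])  # lowest (y, x)
        from porehull._geom import ring_signed_area

        assert ring_signed_area(ring) > 0

    def test_small_cloud_matches_brute_force_polytope(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            pts = rng.normal(size=(rng.integers(5, 13), 3))
            hull = ph.hull_from_track(_track(pts), dims=3)
            vol, area = brute_force_hull_3d(pts)
            assert hull.volume == pytest.approx(vol, rel=1e-9)
            assert hull.surface_area == pytest.approx(area, rel=1e-9)

    def test_small_planar_cloud_matches_brute_force(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            pts = rng.normal(size=(rng.integers(4, 13), 2))
            hull = ph.hull_from_track(_track(pts), dims=2)
            area, perim = brute_force_hull_2d(pts)
            assert hull.volume == pytest.approx(area, rel=1e-9)
            assert hull.surface_area == pytest.approx(perim, rel=1e-9)


class TestDescriptors:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)], np.sqrt(3)),
            ([np.array([np.cos(a), np.sin(a), 0]) + [0, 0, h]
              for a in np.linspace(0, 2 * np.pi, 7)[:-1] for h in (0, 1e-3)], 2.0),
        ],
        ids=["cube-space-diagonal", "hexagon-opposite-vertices"],
    )
    def test_feret_diameter(self, points, expected):
        hull = ph.hull_from_track(_track(points), dims=3)
        assert ph.feret_diameter(hull) == pytest.approx(expected, abs=1e-2)

    def test_feret_of_two_points_is_their_distance(self):
        hull = ph.Hull(dims=3, vertices=np.array([[0.0, 0, 0], [7.0, 0, 0]]),
                       volume=1.0, surface_area=1.0)
        assert ph.feret_diameter(hull) == pytest.approx(7.0)

    @pytest.mark.parametrize(
        "raw, bead, expected", [(8.0, 2.0, 10.0), (10.0, 0.0, 10.0), (10.0, 0.5, 10.5)]
    )
    def test_bead_correction_is_addition(self, raw, bead, expected):
        assert ph.correct_for_bead(raw, bead) == expected

    def test_bead_correction_rejects_negative(self):
        with pytest.raises(ph.DomainError):
            ph.correct_for_bead(-1.0, 1.0)

    def test_sphericity_closed_forms(self):
        r = 3.7
        assert ph.sphericity(4 / 3 * np.pi * r**3, 4 * np.pi * r**2) == pytest.approx(1.0)
        assert ph.sphericity(1.0, 6.0) == pytest.approx(0.80600, abs=1e-4)
        # elongated 1x1x10 box, evaluated by hand
        assert ph.sphericity(10.0, 42.0) == pytest.approx(
            np.pi ** (1 / 3) * 60 ** (2 / 3) / 42
        )

    def test_sphericity_rejects_nonpositive(self):
        with pytest.raises(ph.DomainError):
            ph.sphericity(0.0, 1.0)


class TestHullProperties:
    @given(st.integers(0, 10_000))
    def test_containment_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(30, 3)) * [3.0, 1.0, 2.0]
        hull = ph.hull_from_track(_track(pts), dims=3)
        # every localization on or inside the hull
        from scipy.spatial import ConvexHull

        sh = ConvexHull(hull.vertices)
        inside = (sh.equations[:, :3] @ pts.T + sh.equations[:, 3:]) <= 1e-9
        assert np.all(inside)
        # growing the cloud never shrinks volume or Feret diameter
        sub = ph.hull_from_track(_track(pts[:15]), dims=3)
        assert hull.volume >= sub.volume - 1e-12
        assert ph.feret_diameter(hull) >= ph.feret_diameter(sub) - 1e-12

    def test_projection_never_increases_feret(self, sphere18_models):
        for m in sphere18_models:
            flat = ph.flatten_pore(m)
            assert flat.diameter_2d <= m.diameter_raw + 1e-9

    def test_sphericity_approaches_one_with_sampling(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=(5000, 3))
        pts = v / np.linalg.norm(v, axis=1, keepdims=True)
        sph = [
            ph.build_pore_models(
                ph.TrackSet(tracks=[_track(pts[:n])], bead_diameter=1.0, dims=3)
            ).models[0].sphericity
            for n in (20, 200, 5000)
        ]
        assert sph[0] < sph[1] < sph[2] <= 1.0


class TestBuildPoreModels:
    def test_sphere_recovery_with_correction(self, sphere18_models):
        diams = [m.diameter_corrected for m in sphere18_models]
        assert np.median(diams) == pytest.approx(18.0, rel=0.06)

    def test_short_and_degenerate_tracks_skipped_with_reasons(self):
        good = _track(np.random.default_rng(1).normal(size=(12, 3)), tid="good")
        short = ph.Track("short", [0.0, 1.0, 2.0],
                         [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        flat = _track(np.c_[np.random.default_rng(2).normal(size=(12, 2)),
                            np.zeros(12)], tid="flat")
        ts = ph.TrackSet(tracks=[good, short, flat], bead_diameter=2.0, dims=3)
        result = ph.build_pore_models(ts, min_track_length=10)
        assert [m.track_id for m in result.models] == ["good"]
        reasons = dict(result.skipped)
        assert "short" in reasons["short"]
        assert reasons["flat"] == "degenerate"

    def test_three_point_3d_track_skipped_as_too_short(self):
        tr = ph.Track(1, [0.0, 1.0, 2.0], np.eye(3))
        ts = ph.TrackSet(tracks=[tr], bead_diameter=1.0, dims=3)
        result = ph.build_pore_models(ts, min_track_length=4)
        assert result.models == []
        assert len(result.skipped) == 1

    def test_planar_models_have_area_perimeter_no_sphericity(self):
        panel = ph.simulate_microwell_panel(
            [12.0], ph.DiffusionParams(n_beads=4, n_steps=60, seed=31)
        )
        result = ph.build_pore_models(panel[12.0])
        assert result.models
        for m in result.models:
            assert m.dims == 2
            assert m.volume > 0 and m.surface_area > 0
            assert m.sphericity is None

    def test_z_clipping_flag_excludes_boundary_tracks(self):
        inside = _track(np.random.default_rng(3).uniform(2, 18, size=(12, 3)), tid="in")
        touching = _track(
            np.column_stack([np.random.default_rng(4).normal(size=(12, 2)),
                             np.linspace(0, 5, 12)]), tid="touch")
        ts = ph.TrackSet(tracks=[inside, touching], bead_diameter=1.0, dims=3)
        result = ph.build_pore_models(ts, z_limits=(0.0, 20.0))
        assert [m.track_id for m in result.models] == ["in"]
        assert result.skipped[0][0] == "touch"

    def test_pooled_hull_measures_a_shared_cavity(self):
        panel = ph.simulate_microwell_panel(
            [30.0], ph.DiffusionParams(n_beads=15, n_steps=500, seed=33)
        )
        measured = ph.microwell_measured_diameters(panel)
        assert measured[30.0] == pytest.approx(30.0, rel=0.05)
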