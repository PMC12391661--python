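import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import porehull as ph

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_params() -> ph.DiffusionParams:
    """1 µm beads in water at 300 K, 5 s frames."""
    return ph.DiffusionParams(
        temperature=300.0, viscosity=0.001, bead_radius=0.5e-6, frame_interval=5.0
    )


@pytest.fixture(scope="session")
def sphere18_trackset() -> ph.TrackSet:
    """Beads confined in an 18 µm sphere; reused across hull/flattening tests."""
    params = ph.DiffusionParams(n_beads=12, n_steps=1500, seed=20)
    return ph.simulate_confined(params, ph.Sphere(radius=9.0))


@pytest.fixture(scope="session")
def sphere18_models(sphere18_trackset) -> list:
    return ph.build_pore_models(sphere18_trackset).models


def brute_force_hull_3d(points: np.ndarray) -> tuple[float, float]:
    """Exhaustive convex-polytope construction for small 3D clouds in general
    position: every point triple whose plane has all other points on one side
    is a facet.  Returns (volume, surface area)."""
    from itertools import combinations

    pts = np.asarray(points, dtype=float)
    n = len(pts)
    interior = pts.mean(axis=0)
    volume = 0.0
    area = 0.0
    for i, j, k in combinations(range(n), 3):
        a, b, c = pts[i], pts[j], pts[k]
        normal = np.cross(b - a, c - a)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        side = (pts - a) @ normal
        if np.all(side <= 1e-9) or np.all(side >= -1e-9):
            area += norm / 2.0
            # tetra from the interior point to the facet, oriented outward
            volume += abs(np.dot(a - interior, np.cross(b - interior, c - interior))) / 6.0
    return volume, area


def brute_force_hull_2d(points: np.ndarray) -> tuple[float, float]:
    """Exhaustive 2D hull: every point pair with all others on one side is an
    edge.  Returns (area, perimeter)."""
    from itertools import combinations

    pts = np.asarray(points, dtype=float)
    interior = pts.mean(axis=0)
    area = 0.0
    perimeter = 0.0
    for i, j in combinations(range(len(pts)), 2):
        a, b = pts[i], pts[j]
        d = b - a
        normal = np.array([-d[1], d[0]])
        side = (pts - a) @ normal
        if np.all(side <= 1e-9) or np.all(side >= -1e-9):
            perimeter += np.linalg.norm(d)
            u, v = a - interior, b - interior
            area += abs(u[0] * v[1] - u[1] * v[0]) / 2.0
    return area, perimeter


def fan_triangulation_centroid(ring: np.ndarray) -> tuple[float, float]:
    """Area-weighted centroid via fan triangulation from the first vertex —
    the independent oracle for the shoelace centroid."""
    ring = np.asarray(ring, dtype=float)
    v0 = ring[0]
    acc = np.zeros(2)
    total = 0.0
    for a, b in zip(ring[1:-1], ring[2:]):
        u, v = a - v0, b - v0
        tri_area = (u[0] * v[1] - u[1] * v[0]) / 2.0
        acc += tri_area * (v0 + a + b) / 3.0
        total += tri_area
    return tuple(acc / total)
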