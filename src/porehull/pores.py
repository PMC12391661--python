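"""Convex-hull pore models from bead trajectories.

A bead rattling inside a micropore repeatedly collides with the pore walls;
discarding the time dimension and taking the convex hull of its position
cloud yields a solid geometric model of the pore.  From the hull we report
volume, surface area, Feret diameter (the longest vertex-to-vertex
distance), and sphericity π^(1/3)·(6V)^(2/3)/S.

Because the tracked coordinate is the bead *centroid*, the hull
underestimates the cavity by one bead radius on every side; the reported
diameter is therefore corrected by adding the bead diameter.  Volume and
surface area are reported uncorrected (see the methods note for the caveat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from ._geom import canonical_ring, polygon_centroid
from .errors import DegenerateGeometryError, DomainError, TrackValidationError
from .tracks import Track, TrackSet

__all__ = [
    "Hull",
    "PoreModel",
    "HullBuildResult",
    "hull_from_points",
    "hull_from_track",
    "feret_diameter",
    "correct_for_bead",
    "sphericity",
    "build_pore_models",
    "pooled_pore_model",
    "microwell_measured_diameters",
]


@dataclass
class Hull:
    """Minimal convex polytope of a point cloud.

    In 2D ``vertices`` is a closed CCW ring (k+1, 2), ``volume`` the area
    (µm²) and ``surface_area`` the perimeter (µm).  In 3D ``vertices`` is
    (k, 3), ``faces`` a triangulated facet list indexing into it, ``volume``
    in µm³ and ``surface_area`` in µm².
    """

    dims: int
    vertices: np.ndarray
    volume: float
    surface_area: float
    faces: np.ndarray | None = None


@dataclass
class PoreModel:
    """One reconstructed pore: hull geometry plus derived descriptors.

    ``diameter_corrected = diameter_raw + bead_diameter`` compensates for the
    centroid-based localization of the tracer.  ``sphericity`` is None for
    planar (dims = 2) models.
    """

    track_id: object
    dims: int
    vertices: np.ndarray
    volume: float
    surface_area: float
    diameter_raw: float
    diameter_corrected: float
    sphericity: float | None
    centroid: np.ndarray
    faces: np.ndarray | None = None


@dataclass
class HullBuildResult:
    models: list[PoreModel]
    skipped: list[tuple[object, str]]


def hull_from_points(points: np.ndarray, dims: int, label: object = "?") -> Hull:
    """Convex hull of a raw (n, >=dims) position array."""
    points = np.asarray(points, dtype=float)[:, :dims]
    if points.shape[0] < dims + 1:
        raise TrackValidationError(
            f"track {label!r}: needs >= {dims + 1} localizations for a {dims}D hull"
        )
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"track {label!r}: degenerate point cloud "
            f"({'collinear' if dims == 2 else 'coplanar'})"
        ) from exc
    if dims == 2:
        ring = canonical_ring(points[hull.vertices])  # scipy 2D order is CCW
        return Hull(dims=2, vertices=ring, volume=float(hull.volume),
                    surface_area=float(hull.area))
    # remap facet indices to the hull-vertex numbering
    remap = {v: i for i, v in enumerate(hull.vertices)}
    faces = np.vectorize(remap.__getitem__)(hull.simplices)
    return Hull(dims=3, vertices=points[hull.vertices], volume=float(hull.volume),
                surface_area=float(hull.area), faces=faces)


def hull_from_track(track: Track, dims: int) -> Hull:
    """Convex hull of one track's position coordinates (time discarded)."""
    if dims not in (2, 3):
        raise DomainError("dims must be 2 or 3")
    return hull_from_points(track.xyz, dims, label=track.track_id)


def feret_diameter(hull: Hull) -> float:
    """Longest distance between hull vertices (Feret's diameter), µm."""
    verts = hull.vertices[:-1] if hull.dims == 2 else hull.vertices
    if verts.shape[0] < 2:
        raise DomainError("Feret diameter needs at least 2 vertices")
    return float(pdist(verts).max())


def correct_for_bead(diameter_raw: float, bead_diameter: float) -> float:
    """Add the tracer diameter to a hull diameter (centroid-tracking bias)."""
    if diameter_raw < 0 or bead_diameter < 0:
        raise DomainError("diameters must be >= 0")
    return diameter_raw + bead_diameter


def sphericity(volume: float, surface_area: float) -> float:
    """π^(1/3)·(6V)^(2/3)/S — 1 for a sphere, < 1 for any other shape."""
    if volume <= 0 or surface_area <= 0:
        raise DomainError("volume and surface area must be > 0")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area)


def _hull_centroid(hull: Hull) -> np.ndarray:
    if hull.dims == 2:
        return np.asarray(polygon_centroid(hull.vertices))
    ref = hull.vertices.mean(axis=0)
    total_v = 0.0
    acc = np.zeros(3)
    for ia, ib, ic in hull.faces:
        a, b, c = hull.vertices[ia] - ref, hull.vertices[ib] - ref, hull.vertices[ic] - ref
        v = np.dot(a, np.cross(b, c)) / 6.0
        acc += v * (hull.vertices[ia] + hull.vertices[ib] + hull.vertices[ic] + ref) / 4.0
        total_v += v
    return acc / total_v if total_v != 0 else ref


def _model_from_hull(hull: Hull, track_id: object, bead_diameter: float) -> PoreModel:
    d_raw = feret_diameter(hull)
    return PoreModel(
        track_id=track_id,
        dims=hull.dims,
        vertices=hull.vertices,
        volume=hull.volume,
        surface_area=hull.surface_area,
        diameter_raw=d_raw,
        diameter_corrected=correct_for_bead(d_raw, bead_diameter),
        sphericity=sphericity(hull.volume, hull.surface_area) if hull.dims == 3 else None,
        centroid=_hull_centroid(hull),
        faces=hull.faces,
    )


def build_pore_models(
    trackset: TrackSet,
    min_track_length: int = 10,
    z_limits: tuple[float, float] | None = None,
) -> HullBuildResult:
    """One pore model per eligible track; ineligible tracks are recorded.

    Tracks shorter than ``min_track_length`` grossly under-sample their pore
    and are skipped (but remain available for MSD analysis upstream).  If
    ``z_limits`` is given, tracks touching the imaging-volume boundary in z
    are skipped as clipped.  Degenerate clouds are skipped, never silently
    projected to a lower dimension.
    """
    models: list[PoreModel] = []
    skipped: list[tuple[object, str]] = []
    for track in trackset:
        if track.n < min_track_length:
            skipped.append((track.track_id, f"shorter than {min_track_length} localizations"))
            continue
        if z_limits is not None:
            lo, hi = z_limits
            if track.xyz[:, 2].min() <= lo or track.xyz[:, 2].max() >= hi:
                skipped.append((track.track_id, "touches the z imaging boundary"))
                continue
        try:
            hull = hull_from_track(track, trackset.dims)
        except (DegenerateGeometryError, TrackValidationError):
            reason = "degenerate" if track.n >= trackset.dims + 1 else "too few localizations"
            skipped.append((track.track_id, reason))
            continue
        models.append(_model_from_hull(hull, track.track_id, trackset.bead_diameter))
    return HullBuildResult(models=models, skipped=skipped)


def pooled_pore_model(trackset: TrackSet, label: object = "pooled") -> PoreModel:
    """Hull over the pooled localizations of *all* tracks in the set.

    Appropriate when every track probes the same cavity — e.g. several beads
    drop-cast into one fabricated microwell — where pooling recovers the
    cavity outline far faster than any single track."""
    points = np.vstack([tr.xyz for tr in trackset])
    hull = hull_from_points(points, trackset.dims, label=label)
    return _model_from_hull(hull, label, trackset.bead_diameter)


def microwell_measured_diameters(panel: dict[float, TrackSet]) -> dict[float, float]:
    """Corrected pooled-hull diameter per microwell (keyed by true diameter)."""
    return {
        d: pooled_pore_model(ts, label=f"well_{d}").diameter_corrected
        for d, ts in panel.items()
    }
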