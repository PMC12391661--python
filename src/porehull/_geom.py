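"""Planar polygon primitives shared by the hull, projection and layout code.

Polygons are *closed CCW rings*: an (n+1, 2) array whose first and last
vertex coincide, ordered counterclockwise.  The centroid follows the signed
shoelace construction:

    A  = ½ Σ (x_i·y_{i+1} − x_{i+1}·y_i)
    Cx = 1/(6A) Σ (x_i + x_{i+1})(x_i·y_{i+1} − x_{i+1}·y_i)
    Cy = 1/(6A) Σ (y_i + y_{i+1})(x_i·y_{i+1} − x_{i+1}·y_i)

Orientation is a caller responsibility: a clockwise or open ring raises.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError, PorehullError

__all__ = ["polygon_centroid", "ring_signed_area", "canonical_ring"]


class OrientationError(PorehullError, ValueError):
    """Ring is not a closed counterclockwise polygon."""


def _check_ring(ring: np.ndarray) -> np.ndarray:
    ring = np.asarray(ring, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2 or ring.shape[0] < 4:
        raise OrientationError("ring must be (k, 2) with k >= 4 (triangle + closure)")
    if not np.array_equal(ring[0], ring[-1]):
        raise OrientationError("ring is not closed (first vertex != last vertex)")
    return ring


def ring_signed_area(ring) -> float:
    """Signed shoelace area of a closed ring (positive for CCW)."""
    ring = _check_ring(ring)
    x, y = ring[:-1, 0], ring[:-1, 1]
    xn, yn = ring[1:, 0], ring[1:, 1]
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_centroid(ring) -> tuple[float, float]:
    """Centroid of a closed CCW polygon ring."""
    ring = _check_ring(ring)
    x, y = ring[:-1, 0], ring[:-1, 1]
    xn, yn = ring[1:, 0], ring[1:, 1]
    cross = x * yn - xn * y
    area = 0.5 * float(np.sum(cross))
    if area <= 0:
        raise OrientationError(
            "ring must be counterclockwise with nonzero area; canonicalize first"
        )
    cx = float(np.sum((x + xn) * cross)) / (6.0 * area)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * area)
    return cx, cy


def canonical_ring(vertices: np.ndarray) -> np.ndarray:
    """Canonicalize CCW hull vertices: start at the lowest-(y, x) vertex and
    close the ring.  Input must already be in CCW order (as produced by a 2D
    convex hull); output is (k+1, 2)."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or vertices.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 planar vertices to form a ring")
    start = np.lexsort((vertices[:, 0], vertices[:, 1]))[0]
    rolled = np.roll(vertices, -start, axis=0)
    return np.vstack([rolled, rolled[:1]])
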