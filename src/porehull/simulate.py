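"""Seeded Brownian-dynamics generator for free and confined bead diffusion.

Beads perform independent Gaussian random walks with per-axis step variance
2·D·Δt, where D comes from the Stokes–Einstein relation.  Confined walks are
kept inside a convex geometry *shrunk inward by the bead radius*: the tracked
coordinate is the bead centroid, which can never approach a wall closer than
one radius.  Overshooting steps are folded back across the boundary
(specular reflection for planar facets; radial folding for spherical and
cylindrical walls), which preserves the step-length statistics of the walk.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``, so identical parameters give bit-identical
output, element-wise reproducible across panels.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import ConvexHull

from .errors import DomainError, InfeasibleGeometryError
from .tracks import Track, TrackSet

__all__ = [
    "BOLTZMANN_J_PER_K",
    "DiffusionParams",
    "ConfinementGeometry",
    "Sphere",
    "Cylinder",
    "Box",
    "Polyhedron",
    "stokes_einstein",
    "diffusion_coefficient_um2_s",
    "simulate_free",
    "simulate_confined",
    "simulate_microwell_panel",
]

#: Boltzmann constant, J/K, at the precision used throughout the analysis.
BOLTZMANN_J_PER_K = 1.38e-23


@dataclass(frozen=True)
class DiffusionParams:
    """Physical and acquisition parameters of a tracking run.

    ``bead_radius`` is in metres (as it enters Stokes–Einstein); all emitted
    coordinates are in µm and times in seconds.
    """

    temperature: float = 300.0  # K
    viscosity: float = 1e-3  # Pa·s
    bead_radius: float = 0.5e-6  # m
    frame_interval: float = 5.0  # s
    n_steps: int = 180
    n_beads: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("temperature", "viscosity", "bead_radius", "frame_interval"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        if self.n_steps < 1 or self.n_beads < 1:
            raise DomainError("n_steps and n_beads must be >= 1")

    @property
    def bead_diameter_um(self) -> float:
        return 2.0 * self.bead_radius * 1e6


def stokes_einstein(params: DiffusionParams) -> float:
    """Diffusion coefficient D = k_B·T / (6π·η·r), in m²/s."""
    return BOLTZMANN_J_PER_K * params.temperature / (
        6.0 * np.pi * params.viscosity * params.bead_radius
    )


def diffusion_coefficient_um2_s(params: DiffusionParams) -> float:
    """Stokes–Einstein D converted to µm²/s."""
    return stokes_einstein(params) * 1e12


def _fold_interval(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Triangle-wave fold of values into [lo, hi] (reflecting boundaries)."""
    span = hi - lo
    v = np.mod(u - lo, 2.0 * span)
    return lo + np.where(v > span, 2.0 * span - v, v)


class ConfinementGeometry(ABC):
    """A bounded convex region; the accessible region is the geometry eroded
    inward by the bead radius (``margin``)."""

    kind: str = "none"

    @abstractmethod
    def min_extent(self) -> float:
        """Smallest half-extent; the bead radius must stay below this."""

    @abstractmethod
    def fold(self, points: np.ndarray, margin: float) -> np.ndarray:
        """Reflect points into the accessible region (in place allowed)."""

    @abstractmethod
    def contains(self, points: np.ndarray, margin: float, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask: which points lie inside the accessible region."""

    @abstractmethod
    def sample_uniform(self, n: int, margin: float, rng: np.random.Generator) -> np.ndarray:
        """Draw n points uniformly from the accessible region."""


@dataclass(frozen=True)
class Sphere(ConfinementGeometry):
    radius: float  # µm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "sphere"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise DomainError("sphere radius must be > 0")

    def min_extent(self) -> float:
        return self.radius

    def _accessible(self, margin: float) -> float:
        return self.radius - margin

    def fold(self, points, margin):
        c = np.asarray(self.center)
        d = points - c
        r = np.linalg.norm(d, axis=-1)
        rf = _fold_interval(r, 0.0, self._accessible(margin))
        scale = np.divide(rf, r, out=np.ones_like(r), where=r > 0)
        return c + d * scale[..., None]

    def contains(self, points, margin, tol=1e-9):
        r = np.linalg.norm(points - np.asarray(self.center), axis=-1)
        return r <= self._accessible(margin) + tol

    def sample_uniform(self, n, margin, rng):
        R = self._accessible(margin)
        u = rng.random(n) ** (1.0 / 3.0)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return np.asarray(self.center) + R * u[:, None] * v


@dataclass(frozen=True)
class Cylinder(ConfinementGeometry):
    """Upright circular cylinder (a microwell): radius in the xy plane, axis
    along z, total depth centred on ``center``.  The fabricated microwells
    are 45 µm deep by default."""

    radius: float  # µm
    depth: float = 45.0  # µm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "cylinder"

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.depth <= 0:
            raise DomainError("cylinder radius and depth must be > 0")

    def min_extent(self) -> float:
        return min(self.radius, self.depth / 2.0)

    def fold(self, points, margin):
        c = np.asarray(self.center)
        out = np.array(points, dtype=float, copy=True)
        d = out[..., :2] - c[:2]
        r = np.linalg.norm(d, axis=-1)
        rf = _fold_interval(r, 0.0, self.radius - margin)
        scale = np.divide(rf, r, out=np.ones_like(r), where=r > 0)
        out[..., :2] = c[:2] + d * scale[..., None]
        h = self.depth / 2.0 - margin
        out[..., 2] = _fold_interval(out[..., 2], c[2] - h, c[2] + h)
        return out

    def contains(self, points, margin, tol=1e-9):
        c = np.asarray(self.center)
        r = np.linalg.norm(points[..., :2] - c[:2], axis=-1)
        h = self.depth / 2.0 - margin
        return (r <= self.radius - margin + tol) & (
            np.abs(points[..., 2] - c[2]) <= h + tol
        )

    def sample_uniform(self, n, margin, rng):
        c = np.asarray(self.center)
        R = self.radius - margin
        h = self.depth / 2.0 - margin
        rad = R * np.sqrt(rng.random(n))
        ang = rng.random(n) * 2.0 * np.pi
        z = rng.uniform(-h, h, n)
        return np.column_stack(
            [c[0] + rad * np.cos(ang), c[1] + rad * np.sin(ang), c[2] + z]
        )


@dataclass(frozen=True)
class Box(ConfinementGeometry):
    half_extents: tuple[float, float, float]  # µm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "box"

    def __post_init__(self) -> None:
        if min(self.half_extents) <= 0:
            raise DomainError("box half-extents must be > 0")

    def min_extent(self) -> float:
        return min(self.half_extents)

    def fold(self, points, margin):
        out = np.array(points, dtype=float, copy=True)
        for ax in range(3):
            c = self.center[ax]
            h = self.half_extents[ax] - margin
            out[..., ax] = _fold_interval(out[..., ax], c - h, c + h)
        return out

    def contains(self, points, margin, tol=1e-9):
        ok = np.ones(points.shape[:-1], dtype=bool)
        for ax in range(3):
            h = self.half_extents[ax] - margin
            ok &= np.abs(points[..., ax] - self.center[ax]) <= h + tol
        return ok

    def sample_uniform(self, n, margin, rng):
        lo = np.asarray(self.center) - (np.asarray(self.half_extents) - margin)
        hi = np.asarray(self.center) + (np.asarray(self.half_extents) - margin)
        return rng.uniform(lo, hi, size=(n, 3))


class Polyhedron(ConfinementGeometry):
    """Arbitrary bounded convex polyhedron given by its vertices (µm)."""

    kind = "polyhedron"

    def __init__(self, vertices) -> None:
        vertices = np.asarray(vertices, dtype=float)
        if vertices.ndim != 2 or vertices.shape[1] != 3 or vertices.shape[0] < 4:
            raise DomainError("polyhedron needs >= 4 vertices of dimension 3")
        hull = ConvexHull(vertices)
        # rows: unit outward normal n and offset b with n·x + b <= 0 inside
        self._A = hull.equations[:, :3]
        self._b = hull.equations[:, 3]
        self.vertices = vertices[hull.vertices]
        self._interior = self.vertices.mean(axis=0)

    def min_extent(self) -> float:
        # inradius lower bound: clearance of the vertex centroid
        return float(np.min(-(self._A @ self._interior + self._b)))

    def fold(self, points, margin):
        out = np.atleast_2d(np.array(points, dtype=float, copy=True))
        for _ in range(64):
            viol = self._A @ out.T + (self._b + margin)[:, None]
            worst = np.argmax(viol, axis=0)
            vmax = viol[worst, np.arange(out.shape[0])]
            mask = vmax > 0
            if not mask.any():
                break
            out[mask] -= 2.0 * vmax[mask][:, None] * self._A[worst[mask]]
        else:
            # pathological multi-bounce: project instead of reflecting
            for _ in range(128):
                viol = self._A @ out.T + (self._b + margin)[:, None]
                worst = np.argmax(viol, axis=0)
                vmax = viol[worst, np.arange(out.shape[0])]
                mask = vmax > 0
                if not mask.any():
                    break
                out[mask] -= vmax[mask][:, None] * self._A[worst[mask]]
        return out.reshape(np.shape(points))

    def contains(self, points, margin, tol=1e-9):
        pts = np.atleast_2d(points)
        viol = self._A @ pts.T + (self._b + margin)[:, None]
        return (viol.max(axis=0) <= tol).reshape(np.shape(points)[:-1])

    def sample_uniform(self, n, margin, rng):
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        out = np.empty((0, 3))
        while out.shape[0] < n:
            cand = rng.uniform(lo, hi, size=(max(n, 64), 3))
            out = np.vstack([out, cand[self.contains(cand, margin)]])
        return out[:n]


def _trackset_from_paths(traj: np.ndarray, params: DiffusionParams, dims: int) -> TrackSet:
    """traj has shape (n_steps+1, n_beads, 3)."""
    t = np.arange(traj.shape[0]) * params.frame_interval
    tracks = [Track(i, t, traj[:, i, :].copy()) for i in range(traj.shape[1])]
    return TrackSet(
        tracks=tracks,
        frame_interval=params.frame_interval,
        bead_diameter=params.bead_diameter_um,
        dims=dims,
    )


def _apply_observation_effects(
    traj: np.ndarray,
    rng: np.random.Generator,
    noise_sigma: float,
    z_quantum: float | None,
) -> np.ndarray:
    if noise_sigma > 0:
        traj = traj + rng.normal(0.0, noise_sigma, traj.shape)
    if z_quantum:
        traj = traj.copy()
        traj[..., 2] = np.round(traj[..., 2] / z_quantum) * z_quantum
    return traj


def simulate_free(
    params: DiffusionParams,
    *,
    noise_sigma: float = 0.0,
    z_quantum: float | None = None,
) -> TrackSet:
    """Free 3D diffusion: each bead is an unconstrained Gaussian walk from the
    origin with per-axis step variance 2·D·Δt (µm²)."""
    D = diffusion_coefficient_um2_s(params)
    sigma = np.sqrt(2.0 * D * params.frame_interval)
    rng = np.random.default_rng(params.seed)
    steps = rng.normal(0.0, sigma, (params.n_steps, params.n_beads, 3))
    traj = np.zeros((params.n_steps + 1, params.n_beads, 3))
    np.cumsum(steps, axis=0, out=traj[1:])
    traj = _apply_observation_effects(traj, rng, noise_sigma, z_quantum)
    return _trackset_from_paths(traj, params, dims=3)


def simulate_confined(
    params: DiffusionParams,
    geometry: ConfinementGeometry,
    *,
    noise_sigma: float = 0.0,
    z_quantum: float | None = None,
) -> TrackSet:
    """Diffusion confined in a convex geometry, bead centroid kept at least
    one bead radius away from every wall.  Initial positions are uniform in
    the accessible region."""
    margin = params.bead_radius * 1e6  # µm
    if margin >= geometry.min_extent():
        raise InfeasibleGeometryError(
            f"bead radius {margin} µm does not fit inside {geometry.kind} "
            f"geometry of half-extent {geometry.min_extent()} µm"
        )
    D = diffusion_coefficient_um2_s(params)
    sigma = np.sqrt(2.0 * D * params.frame_interval)
    rng = np.random.default_rng(params.seed)
    pos = geometry.sample_uniform(params.n_beads, margin, rng)
    traj = np.empty((params.n_steps + 1, params.n_beads, 3))
    traj[0] = pos
    for s in range(1, params.n_steps + 1):
        pos = geometry.fold(pos + rng.normal(0.0, sigma, pos.shape), margin)
        traj[s] = pos
    traj = _apply_observation_effects(traj, rng, noise_sigma, z_quantum)
    return _trackset_from_paths(traj, params, dims=3)


def simulate_microwell_panel(
    diameters,
    params: DiffusionParams,
    depth: float = 45.0,
) -> dict[float, TrackSet]:
    """One planar TrackSet per microwell diameter.

    Each well is an upright cylinder of the given diameter (µm) and depth;
    motion is simulated in 3D and observed in 2D (z discarded), emulating
    widefield tracking of beads drop-cast into fabricated wells.  Per-well
    seeds are spawned deterministically from the master seed.
    """
    diameters = [float(d) for d in diameters]
    children = np.random.SeedSequence(params.seed).spawn(len(diameters))
    panel: dict[float, TrackSet] = {}
    for d, child in zip(diameters, children):
        geom = Cylinder(radius=d / 2.0, depth=depth)
        sub = replace(params, seed=int(child.generate_state(1)[0]))
        ts3 = simulate_confined(sub, geom)
        tracks = []
        for tr in ts3:
            xyz = tr.xyz.copy()
            xyz[:, 2] = 0.0
            tracks.append(Track(tr.track_id, tr.t, xyz))
        panel[d] = TrackSet(
            tracks=tracks,
            frame_interval=ts3.frame_interval,
            bead_diameter=ts3.bead_diameter,
            dims=2,
        )
    return panel
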