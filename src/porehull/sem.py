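"""Simulated 2D SEM-like pore sections from 3D pore models.

A cryo-SEM micrograph shows a planar cross-section, so it samples each pore
in two dimensions only.  To emulate that from tracking-derived 3D pore
models, a random subset of pores is drawn under a total-volume budget
(normalizing the sampled gel volume across conditions), each selected pore
is flattened by dropping the z coordinate of its hull vertices and
re-hulling in the plane, and pores below the micrograph's resolution floor
are filtered out.  The resulting 2D diameter distribution can then be
compared against a reference distribution with a Mann–Whitney U test.

Because projection can only contract distances, a flattened Feret diameter
never exceeds its 3D parent — the mechanism by which 2D imaging
underestimates true pore diameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._geom import polygon_centroid
from .errors import DomainError, TrackValidationError
from .pores import Hull, PoreModel, feret_diameter, hull_from_points

__all__ = [
    "FlatPore",
    "SamplingPolicy",
    "FilterResult",
    "ComparisonResult",
    "sample_pores_by_volume",
    "flatten_pore",
    "flatten_pores",
    "apply_resolution_filter",
    "compare_distributions",
    "bonferroni",
]


@dataclass
class FlatPore:
    """A 3D pore flattened onto the xy plane.

    ``vertices_2d`` is a closed CCW ring (µm); ``area`` in µm²;
    ``diameter_2d`` the planar Feret diameter, never larger than the parent
    3D diameter.
    """

    source_track_id: object
    vertices_2d: np.ndarray
    area: float
    diameter_2d: float
    centroid: tuple[float, float]


@dataclass(frozen=True)
class SamplingPolicy:
    """Selection and filtering rules for the simulated SEM section.

    ``volume_budget`` caps the summed volume of the sampled pores (µm³);
    ``min_diameter`` is the resolution floor of the reference micrographs
    (no default — it comes from the imaging data); pores under ``min_area``
    are discarded as undetectable.
    """

    volume_budget: float = 300_000.0  # µm³
    min_diameter: float | None = None  # µm
    min_area: float = 10.0  # µm²
    seed: int = 0

    def __post_init__(self) -> None:
        if self.volume_budget <= 0:
            raise DomainError("volume_budget must be > 0")


@dataclass
class FilterResult:
    kept: list[FlatPore]
    removed_by_diameter: int
    removed_by_area: int


@dataclass
class ComparisonResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def sample_pores_by_volume(
    pores: list[PoreModel], policy: SamplingPolicy
) -> tuple[list[PoreModel], float]:
    """Random without-replacement pore selection under the volume budget.

    Pores are visited in a seeded random order and accumulated while the
    running total stays within the budget; selection stops at the first pore
    that would overshoot, leaving the total equal to or a little below the
    budget.  Returns (selection, total volume).
    """
    if not pores:
        return [], 0.0
    rng = np.random.default_rng(policy.seed)
    order = rng.permutation(len(pores))
    selected: list[PoreModel] = []
    total = 0.0
    for i in order:
        if total + pores[i].volume > policy.volume_budget:
            break
        selected.append(pores[i])
        total += pores[i].volume
    return selected, total


def flatten_pore(pore: PoreModel) -> FlatPore:
    """Drop z from the 3D hull vertices and re-hull in the xy plane."""
    if pore.dims != 3:
        raise DomainError("flatten_pore expects a 3D pore model")
    hull2: Hull = hull_from_points(pore.vertices[:, :2], dims=2, label=pore.track_id)
    ring = hull2.vertices
    return FlatPore(
        source_track_id=pore.track_id,
        vertices_2d=ring,
        area=hull2.volume,
        diameter_2d=feret_diameter(hull2),
        centroid=polygon_centroid(ring),
    )


def flatten_pores(pores: list[PoreModel]) -> list[FlatPore]:
    return [flatten_pore(p) for p in pores]


def apply_resolution_filter(
    flats: list[FlatPore], policy: SamplingPolicy
) -> FilterResult:
    """Drop pores below the diameter and/or area floors; count removals per
    rule (a pore failing both counts against the diameter rule)."""
    min_d = policy.min_diameter or 0.0
    min_a = policy.min_area or 0.0
    kept: list[FlatPore] = []
    by_d = by_a = 0
    for f in flats:
        if f.diameter_2d < min_d:
            by_d += 1
        elif f.area < min_a:
            by_a += 1
        else:
            kept.append(f)
    return FilterResult(kept=kept, removed_by_diameter=by_d, removed_by_area=by_a)


def compare_distributions(a, b) -> ComparisonResult:
    """Two-sided Mann–Whitney U test between two diameter samples (µm)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise TrackValidationError("both samples must contain at least one value")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def bonferroni(p_values) -> list[float]:
    """Bonferroni-adjusted p-values for a family of comparisons."""
    m = len(p_values)
    return [min(1.0, float(p) * m) for p in p_values]
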