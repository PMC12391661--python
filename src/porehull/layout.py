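"""Pseudo-2D pore maps: overlap-free layouts of flattened pores.

Flattening pores from different z planes makes them overlap when drawn in
their original xy positions, so the pores are re-laid out while preserving
shape, size and orientation (pure translation only).  Two layouts are
offered:

* **fixed_gap** — pores left to right with a fixed gap (default 10 µm)
  between consecutive bounding boxes;
* **packed** — a placeholder circle per pore, with diameter equal to the
  pore's planar Feret diameter, packed densely by a deterministic
  front-chain circle-packing algorithm; each pore is then translated so its
  polygon centroid sits on its circle's centre, and the circles discarded.

The front-chain packing places every circle tangent to two circles on the
current front and guarantees no two circles overlap (tolerance 1e-9 µm);
placement order follows input order, so results are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._geom import polygon_centroid  # re-exported: shoelace centroid of a CCW ring
from .errors import DomainError
from .sem import FlatPore

__all__ = [
    "polygon_centroid",
    "LayoutPlan",
    "pack_circles",
    "reposition_pore",
    "layout_pores",
    "render_layout",
]

_EPS = 1e-10  # overlap slop; above float noise, below the 1e-9 contract


@dataclass
class LayoutPlan:
    """Where each pore goes: target centroid per pore index, and (in packed
    mode) the placeholder circles as (cx, cy, r) triples."""

    mode: str
    gap: float
    placements: dict
    circles: list[tuple[float, float, float]] | None = None


class _Node:
    __slots__ = ("x", "y", "r", "next", "prev")

    def __init__(self, r: float) -> None:
        self.x = 0.0
        self.y = 0.0
        self.r = r
        self.next = None
        self.prev = None


def _place(b: _Node, a: _Node, c: _Node) -> None:
    """Position c externally tangent to both a and b (front-chain step)."""
    dx, dy = b.x - a.x, b.y - a.y
    d2 = dx * dx + dy * dy
    if d2:
        a2 = (a.r + c.r) ** 2
        b2 = (b.r + c.r) ** 2
        if a2 > b2:
            x = (d2 + b2 - a2) / (2.0 * d2)
            y = math.sqrt(max(0.0, b2 / d2 - x * x))
            c.x = b.x - x * dx - y * dy
            c.y = b.y - x * dy + y * dx
        else:
            x = (d2 + a2 - b2) / (2.0 * d2)
            y = math.sqrt(max(0.0, a2 / d2 - x * x))
            c.x = a.x + x * dx - y * dy
            c.y = a.y + x * dy + y * dx
    else:
        c.x = a.x + c.r
        c.y = a.y


def _intersects(a: _Node, b: _Node) -> bool:
    dr = a.r + b.r - _EPS
    dx, dy = b.x - a.x, b.y - a.y
    return dr > 0 and dr * dr > dx * dx + dy * dy


def _score(node: _Node) -> float:
    a, b = node, node.next
    ab = a.r + b.r
    dx = (a.x * b.r + b.x * a.r) / ab
    dy = (a.y * b.r + b.y * a.r) / ab
    return dx * dx + dy * dy


def pack_circles(diameters) -> np.ndarray:
    """Deterministic front-chain circle packing.

    Returns an (n, 2) array of centres such that no two circles overlap and
    every circle after the second is tangent to at least one earlier circle.
    Input order is preserved (the algorithm is order-sensitive).
    """
    ds = [float(d) for d in diameters]
    if any(not (d > 0) or not math.isfinite(d) for d in ds):
        raise DomainError("circle diameters must be positive and finite")
    n = len(ds)
    if n == 0:
        return np.empty((0, 2))
    nodes = [_Node(d / 2.0) for d in ds]
    a = nodes[0]
    if n == 1:
        return np.array([[0.0, 0.0]])
    b = nodes[1]
    a.x, b.x, b.y = -b.r, a.r, 0.0
    if n == 2:
        return np.array([[a.x, a.y], [b.x, b.y]])
    c = nodes[2]
    _place(b, a, c)
    a.next = c.prev = b
    b.next = a.prev = c
    c.next = b.prev = a

    i = 3
    while i < n:
        cc = nodes[i]
        _place(a, b, cc)
        # scan the front chain for an intersection, nearest side first
        j, k = b.next, a.prev
        sj, sk = b.r, a.r
        retry = False
        while True:
            if sj <= sk:
                if _intersects(j, cc):
                    b = j
                    a.next, b.prev = b, a
                    retry = True
                    break
                sj += j.r
                j = j.next
            else:
                if _intersects(k, cc):
                    a = k
                    a.next, b.prev = b, a
                    retry = True
                    break
                sk += k.r
                k = k.prev
            if j is k.next:
                break
        if retry:
            continue
        # insert cc between a and b on the front
        cc.prev, cc.next = a, b
        a.next = b.prev = cc
        b = cc
        # restart the chain at the pair closest to the packing centre
        best, best_score = a, _score(a)
        node = cc.next
        while node is not cc:
            s = _score(node)
            if s < best_score:
                best, best_score = node, s
            node = node.next
        a = best
        b = a.next
        i += 1
    return np.array([[nd.x, nd.y] for nd in nodes])


def reposition_pore(flat: FlatPore, target) -> FlatPore:
    """Translate a pore so its centroid lands on ``target``.

    Pure rigid translation: shape, area and diameter are preserved exactly.
    """
    tx, ty = float(target[0]), float(target[1])
    delta = np.array([tx - flat.centroid[0], ty - flat.centroid[1]])
    return replace(flat, vertices_2d=flat.vertices_2d + delta, centroid=(tx, ty))


def layout_pores(
    flats: list[FlatPore], mode: str = "packed", gap: float = 10.0
) -> tuple[LayoutPlan, list[FlatPore]]:
    """Lay out flattened pores without overlaps.

    fixed_gap: consecutive bounding boxes separated by ``gap`` along x,
    vertically centred.  packed: placeholder circles with the pores' Feret
    diameters are packed and each pore translated onto its circle centre.
    """
    if not flats:
        raise DomainError("cannot lay out an empty pore list")
    if mode == "fixed_gap":
        placements: dict = {}
        placed = []
        cursor = 0.0
        for i, f in enumerate(flats):
            ring = f.vertices_2d
            xmin, ymin = ring.min(axis=0)
            xmax, ymax = ring.max(axis=0)
            dx = cursor - xmin
            dy = -(ymin + ymax) / 2.0
            target = (f.centroid[0] + dx, f.centroid[1] + dy)
            placements[i] = target
            placed.append(reposition_pore(f, target))
            cursor += (xmax - xmin) + gap
        return LayoutPlan(mode=mode, gap=gap, placements=placements), placed
    if mode == "packed":
        centers = pack_circles([f.diameter_2d for f in flats])
        placements = {i: (float(c[0]), float(c[1])) for i, c in enumerate(centers)}
        placed = [reposition_pore(f, placements[i]) for i, f in enumerate(flats)]
        circles = [
            (float(c[0]), float(c[1]), f.diameter_2d / 2.0)
            for c, f in zip(centers, flats)
        ]
        return LayoutPlan(mode=mode, gap=gap, placements=placements, circles=circles), placed
    raise DomainError(f"unknown layout mode: {mode!r}")


def render_layout(
    flats: list[FlatPore],
    path,
    *,
    um_per_px: float = 1.0,
    scale_bar_um: float = 50.0,
    dpi: int = 150,
) -> None:
    """Draw pore outlines to an SVG or PNG file at a stated µm-per-pixel
    scale, with a scale bar.  An empty list yields a blank canvas with the
    scale bar only."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon

    if flats:
        allv = np.vstack([f.vertices_2d for f in flats])
        xmin, ymin = allv.min(axis=0)
        xmax, ymax = allv.max(axis=0)
    else:
        xmin = ymin = 0.0
        xmax = ymax = max(scale_bar_um * 2.0, 1.0)
    margin = 0.05 * max(xmax - xmin, ymax - ymin, scale_bar_um)
    xmin, xmax = xmin - margin, xmax + margin
    ymin, ymax = ymin - margin, ymax + margin

    w_px = max((xmax - xmin) / um_per_px, 100.0)
    h_px = max((ymax - ymin) / um_per_px, 100.0)
    fig, ax = plt.subplots(figsize=(w_px / dpi, h_px / dpi), dpi=dpi)
    for f in flats:
        ax.add_patch(Polygon(f.vertices_2d[:-1], closed=True, fill=False,
                             edgecolor="tab:blue", linewidth=0.8))
    # scale bar, bottom left
    bx = xmin + margin
    by = ymin + margin / 2.0
    ax.plot([bx, bx + scale_bar_um], [by, by], color="black", linewidth=3)
    ax.text(bx, by + margin / 4.0, f"{scale_bar_um:g} µm", fontsize=8)
    ax.set_xlim(xmin, xmax)
    ax.set_ylim(ymin, ymax)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
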