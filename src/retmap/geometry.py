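"""Retina and colliculus layouts, the retinotopic mapping, and spatial queries.

Conventions
-----------
* Retina: unit-disk coordinates.  x is the nasal-temporal (NT) axis with
  temporal = +1, y is the dorsal-ventral (DV) axis.  A physical radius in mm
  scales positions for wave propagation.
* Colliculus: planar coordinates in µm.  Origin at the anterior-medial corner;
  x (AP axis) increases posteriorly over ``[0, ap_length]``; y (ML axis) is
  centred on 0.  The outline is a gently tapered ellipse, posterior end
  narrower, with AP:ML aspect 1.6 by default.
* Temporal retina maps to anterior colliculus (high-EphA axons are repelled
  from the posterior, ephrinA-rich end), nasal to posterior; DV maps to ML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DENDRITE_RADIUS_UM = 25.0
LINEAR_DENSITY_PER_MM = 167.0
PLANAR_DENSITY_PER_MM2 = LINEAR_DENSITY_PER_MM**2  # ~27.9 K cells/mm²
CELL_SPACING_UM = 1000.0 / LINEAR_DENSITY_PER_MM   # ~6 µm

CLASS_GENERIC, CLASS_ON, CLASS_OFF = 0, 1, 2
_CLASS_NAMES = {CLASS_GENERIC: "generic", CLASS_ON: "ON", CLASS_OFF: "OFF"}


@dataclass
class RetinaLayout:
    """Quasi-uniform packing of RGC somas on the unit disk."""

    xy: np.ndarray                 # (n, 2) unit-disk coordinates
    eye: str = "L"
    cell_class: np.ndarray | None = None   # per-cell class codes
    radius_mm: float = 1.1

    def __post_init__(self) -> None:
        if self.cell_class is None:
            self.cell_class = np.full(len(self.xy), CLASS_GENERIC, dtype=np.int8)

    @property
    def n_cells(self) -> int:
        return len(self.xy)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    @property
    def xy_mm(self) -> np.ndarray:
        return self.xy * self.radius_mm

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.radius_mm**2)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "x": self.xy[:, 0],
                "y": self.xy[:, 1],
                "eye": self.eye,
                "cell_class": [_CLASS_NAMES[c] for c in self.cell_class],
            }
        )


def build_retina(
    n_cells: int,
    eye: str = "L",
    class_scheme: str = "generic",
    seed: int | np.random.SeedSequence = 0,
    radius_mm: float = 1.1,
) -> RetinaLayout:
    """Place ``n_cells`` RGCs quasi-uniformly on the unit disk.

    A sunflower (Fermat spiral) packing gives an even, isotropic layout with
    exactly ``n_cells`` somas; a small seeded jitter breaks the residual
    lattice symmetry.  For ``class_scheme='onoff'`` ON and OFF cells alternate
    along the spiral, so every neighbourhood contains both classes.
    """
    if n_cells < 10:
        raise ValueError(f"n_cells must be >= 10, got {n_cells}")
    rng = np.random.default_rng(seed)
    k = np.arange(n_cells) + 0.5
    r = np.sqrt(k / n_cells)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = k * golden
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    xy += rng.normal(0.0, 0.25 / np.sqrt(n_cells), size=xy.shape)
    norm = np.hypot(xy[:, 0], xy[:, 1])
    outside = norm > 1.0
    if outside.any():
        xy[outside] /= norm[outside, None] * (1.0 + 1e-9)

    if class_scheme == "generic":
        classes = np.full(n_cells, CLASS_GENERIC, dtype=np.int8)
    elif class_scheme == "onoff":
        classes = np.where(np.arange(n_cells) % 2 == 0, CLASS_ON, CLASS_OFF).astype(
            np.int8
        )
    else:
        raise ValueError(f"unknown class_scheme {class_scheme!r}")
    return RetinaLayout(xy=xy, eye=eye, cell_class=classes, radius_mm=radius_mm)


# ---------------------------------------------------------------------------
# Colliculus

_TAPER = 0.25  # posterior ML half-width reduced by this fraction


def _unit_half_width(xi: np.ndarray | float) -> np.ndarray | float:
    """ML half-width of the outline at AP position ``xi`` in [-1, 1], for a
    domain with unit semi-axes (taper narrows the posterior end)."""
    xi = np.clip(xi, -1.0, 1.0)
    return np.sqrt(np.maximum(0.0, 1.0 - np.asarray(xi) ** 2)) * (
        1.0 - _TAPER * (np.asarray(xi) + 1.0) / 2.0
    )


def _unit_outline_area() -> float:
    xi = np.linspace(-1.0, 1.0, 2001)
    return float(np.trapezoid(2.0 * _unit_half_width(xi), xi))  # per unit a*b


_UNIT_AREA = _unit_outline_area()  # area = _UNIT_AREA * a * b for semi-axes a, b


@dataclass
class ColliculusLayout:
    """Densely packed collicular cells on a tapered asymmetric domain."""

    xy: np.ndarray                  # (n, 2) in µm
    ap_length: float                # L_c, µm
    ml_width: float                 # full ML width at the widest point, µm
    dendritic_radius: float = DENDRITE_RADIUS_UM
    spacing: float = CELL_SPACING_UM

    @property
    def n_cells(self) -> int:
        return len(self.xy)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def half_width(self, x_um: np.ndarray | float) -> np.ndarray | float:
        xi = 2.0 * np.asarray(x_um, dtype=float) / self.ap_length - 1.0
        return (self.ml_width / 2.0) * _unit_half_width(xi)

    def contains(self, x_um, y_um, margin: float = 0.0):
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(y_um, dtype=float)
        inside_x = (x >= 0.0) & (x <= self.ap_length)
        return inside_x & (np.abs(y) <= self.half_width(np.clip(x, 0, self.ap_length)) - margin)

    @property
    def centroid(self) -> np.ndarray:
        return self.xy.mean(axis=0)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "x": self.xy[:, 0], "y": self.xy[:, 1]}
        )


def build_colliculus(
    n_cells: int,
    aspect: float = 1.6,
    seed: int | np.random.SeedSequence = 0,
) -> ColliculusLayout:
    """Construct a collicular layout of ~``n_cells`` somas.

    Cells sit on a jittered square lattice at 167 cells/mm linear density
    (~6 µm spacing, ~27,900 cells/mm²).  The domain is a tapered ellipse with
    AP longer than ML by ``aspect``; its area is ``n_cells`` / 27,900 mm² so
    planar density is scale-invariant.
    """
    if n_cells < 100:
        raise ValueError(f"n_cells must be >= 100, got {n_cells}")
    if aspect <= 0:
        raise ValueError("aspect must be positive")
    rng = np.random.default_rng(seed)
    area_um2 = n_cells / PLANAR_DENSITY_PER_MM2 * 1e6
    # area = _UNIT_AREA * (L/2) * (W/2) with W = L / aspect
    ap_length = float(np.sqrt(4.0 * area_um2 * aspect / _UNIT_AREA))
    ml_width = ap_length / aspect

    nx = int(np.ceil(ap_length / CELL_SPACING_UM))
    ny = int(np.ceil(ml_width / CELL_SPACING_UM))
    gx = (np.arange(nx) + 0.5) * CELL_SPACING_UM
    gy = (np.arange(-ny // 2, ny // 2 + 1) + 0.5) * CELL_SPACING_UM
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pts += rng.normal(0.0, 0.5, size=pts.shape)  # 0.5 µm jitter breaks ties
    layout = ColliculusLayout(xy=pts, ap_length=ap_length, ml_width=ml_width)
    keep = layout.contains(pts[:, 0], pts[:, 1])
    layout.xy = pts[keep]
    return layout


# ---------------------------------------------------------------------------
# Retinotopic mapping

_ML_MARGIN = 0.9  # DV extremes map to this fraction of the local half-width


def retinotopic_target(
    retina_xy: np.ndarray, colliculus: ColliculusLayout
) -> np.ndarray:
    """Map retinal unit-disk positions to their retinotopically correct
    termination zones (RC-TZ) in collicular µm coordinates.

    Temporal retina (NT = +1) maps to the anterior pole (AP = 0), nasal to
    posterior; the DV coordinate maps to ML, scaled by the local half-width so
    the image stays inside the tapered outline.
    """
    xy = np.atleast_2d(np.asarray(retina_xy, dtype=float))
    nt, dv = xy[:, 0], xy[:, 1]
    x_c = colliculus.ap_length * (1.0 - nt) / 2.0
    y_c = dv * _ML_MARGIN * colliculus.half_width(x_c)
    out = np.column_stack([x_c, y_c])
    return out if np.asarray(retina_xy).ndim == 2 else out[0]


# ---------------------------------------------------------------------------
# Spatial grid

class SpatialGrid:
    """10×10 µm partition of the colliculus indexing dendritic disks.

    Every collicular dendrite (25 µm radius disk) is registered in exactly the
    grid squares it geometrically overlaps; axon segments query the grid for
    the dendrites they can synapse onto.
    """

    def __init__(self, colliculus: ColliculusLayout, cell_size: float = 10.0):
        self.colliculus = colliculus
        self.cell_size = float(cell_size)
        r = colliculus.dendritic_radius
        self.x0 = -r - self.cell_size
        self.y0 = -colliculus.ml_width / 2.0 - r - self.cell_size
        self.nx = int(np.ceil((colliculus.ap_length + 2 * r + 2 * self.cell_size - 0) / self.cell_size)) + 1
        self.ny = int(np.ceil((colliculus.ml_width + 2 * r + 2 * self.cell_size) / self.cell_size)) + 1
        self._build_dendrite_index()

    # -- indexing helpers ---------------------------------------------------
    def square_of(self, x_um, y_um):
        """Flat index of the grid square containing each point."""
        ix = np.floor((np.asarray(x_um, dtype=float) - self.x0) / self.cell_size).astype(np.int64)
        iy = np.floor((np.asarray(y_um, dtype=float) - self.y0) / self.cell_size).astype(np.int64)
        if np.any((ix < 0) | (ix >= self.nx) | (iy < 0) | (iy >= self.ny)):
            raise ValueError("position outside the gridded domain")
        return ix * self.ny + iy

    @property
    def n_squares(self) -> int:
        return self.nx * self.ny

    def _square_overlaps_disk(self, ix, iy, cx, cy, r) -> np.ndarray:
        xlo = self.x0 + ix * self.cell_size
        ylo = self.y0 + iy * self.cell_size
        dx = np.maximum(np.maximum(xlo - cx, 0.0), cx - (xlo + self.cell_size))
        dy = np.maximum(np.maximum(ylo - cy, 0.0), cy - (ylo + self.cell_size))
        return dx * dx + dy * dy <= r * r

    def _build_dendrite_index(self) -> None:
        coll = self.colliculus
        r = coll.dendritic_radius
        span = int(np.ceil(r / self.cell_size)) + 1
        offs = np.arange(-span, span + 1)
        ox, oy = np.meshgrid(offs, offs, indexing="ij")
        ox, oy = ox.ravel(), oy.ravel()

        cx, cy = coll.xy[:, 0], coll.xy[:, 1]
        cix = np.floor((cx - self.x0) / self.cell_size).astype(np.int64)
        ciy = np.floor((cy - self.y0) / self.cell_size).astype(np.int64)
        # candidate (cell, square) pairs
        ix = (cix[:, None] + ox[None, :]).ravel()
        iy = (ciy[:, None] + oy[None, :]).ravel()
        cid = np.repeat(coll.cell_ids, len(ox))
        ok = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        ix, iy, cid = ix[ok], iy[ok], cid[ok]
        ok = self._square_overlaps_disk(ix, iy, cx[cid], cy[cid], r)
        ix, iy, cid = ix[ok], iy[ok], cid[ok]
        flat = ix * self.ny + iy
        order = np.argsort(flat, kind="stable")
        flat, cid = flat[order], cid[order]
        self._sq_indptr = np.searchsorted(flat, np.arange(self.n_squares + 1))
        self._sq_cells = cid

    def cells_in_square(self, flat_idx: int) -> np.ndarray:
        return self._sq_cells[self._sq_indptr[flat_idx]: self._sq_indptr[flat_idx + 1]]

    # -- segment queries ----------------------------------------------------
    def _squares_on_segment(self, x1, y1, x2, y2) -> np.ndarray:
        """Flat indices of all squares the segment passes through (supercover)."""
        n = max(2, int(np.ceil(np.hypot(x2 - x1, y2 - y1) / (self.cell_size / 4.0))) + 1)
        t = np.linspace(0.0, 1.0, n)
        xs = x1 + (x2 - x1) * t
        ys = y1 + (y2 - y1) * t
        return np.unique(self.square_of(xs, ys))

    def overlapping_dendrites(self, x1, y1, x2, y2) -> np.ndarray:
        """Collicular cells whose dendritic disk intersects the segment.

        Candidates come from the dendrite index of the squares the segment
        passes through; an exact point-to-segment distance test filters them,
        so the result equals brute-force geometric intersection.
        """
        squares = self._squares_on_segment(x1, y1, x2, y2)
        cand = np.unique(
            np.concatenate([self.cells_in_square(s) for s in squares])
            if len(squares)
            else np.empty(0, dtype=np.int64)
        )
        if len(cand) == 0:
            return cand
        pts = self.colliculus.xy[cand]
        d = point_segment_distance(pts[:, 0], pts[:, 1], x1, y1, x2, y2)
        return cand[d <= self.colliculus.dendritic_radius]


def point_segment_distance(px, py, x1, y1, x2, y2):
    """Euclidean distance from points to a line segment."""
    px, py = np.asarray(px, dtype=float), np.asarray(py, dtype=float)
    vx, vy = x2 - x1, y2 - y1
    L2 = vx * vx + vy * vy
    if L2 == 0.0:
        return np.hypot(px - x1, py - y1)
    t = np.clip(((px - x1) * vx + (py - y1) * vy) / L2, 0.0, 1.0)
    return np.hypot(px - (x1 + t * vx), py - (y1 + t * vy))
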