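"""Grids, media, and initial-pressure phantoms.

The simulation domain is a regular 2D grid with the origin at the top-left
corner: row indices increase downward (the depth direction, Y) and column
indices increase rightward (X).  Cell ``(r, c)`` covers the physical square
``[r*dx, (r+1)*dx) x [c*dx, (c+1)*dx)`` in mm, so a slab occupying inclusive
rows ``r0..r1`` has physical depth bounds ``(r0*dx, (r1+1)*dx)`` and
thickness ``(r1 - r0 + 1)*dx``.

A :class:`Phantom` carries both the rasterized initial pressure map ``p0``
and a ledger of the shapes that produced it; re-rasterizing the ledger must
reproduce ``p0`` exactly, which tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError, PlacementInfeasibleError

__all__ = [
    "Grid",
    "Medium",
    "SlabShape",
    "DiscShape",
    "Phantom",
    "build_grid",
    "new_phantom",
    "add_slab",
    "scatter_discs",
    "discrimination_phantom",
    "SIM_GRID_N",
    "SIM_DX_MM",
    "SLAB_ROWS",
    "SLAB_COLS",
    "SENSOR_ROW",
    "POINT_SENSOR_COL",
    "PLANAR_SENSOR_COLS",
]

# Reference discrimination scene (0-based inclusive index bounds; in
# 1-based MATLAB-style indexing the slab would read rows 59-69 and the
# sensor row 30).  With cells covering [i*dx, (i+1)*dx), the physical
# bounds are: slab depth (29.0, 34.5) mm, sensor strip (14.5, 15.0) mm at
# dx = 0.5 mm.
SIM_GRID_N = 128
SIM_DX_MM = 0.5
SLAB_ROWS = (58, 68)
SLAB_COLS = (23, 103)
SENSOR_ROW = 29
POINT_SENSOR_COL = 63
PLANAR_SENSOR_COLS = (28, 98)


@dataclass(frozen=True)
class Grid:
    """Regular isotropic 2D grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Number of grid points along Y (depth) and X.
    dx : float
        Isotropic spacing in mm.
    """

    n_rows: int
    n_cols: int
    dx: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidArgumentError("grid dimensions must be >= 1")
        if not self.dx > 0:
            raise InvalidArgumentError("grid spacing must be positive")

    @property
    def extent_x(self) -> float:
        """Field-of-view width in mm (X)."""
        return self.n_cols * self.dx

    @property
    def extent_y(self) -> float:
        """Field-of-view height in mm (Y)."""
        return self.n_rows * self.dx

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) center coordinates of every cell, in mm."""
        y = (np.arange(self.n_rows) + 0.5) * self.dx
        x = (np.arange(self.n_cols) + 0.5) * self.dx
        return y, x


@dataclass(frozen=True)
class Medium:
    """Homogeneous lossless acoustic medium.

    ``sound_speed`` is in mm/us (1500 m/s == 1.5 mm/us).  ``density`` is
    carried as metadata only: the propagation model is lossless and
    homogeneous, so density never enters the pressure field evolution.
    """

    sound_speed: float = 1.5
    density: float = 1000.0

    def __post_init__(self) -> None:
        if not self.sound_speed > 0:
            raise InvalidArgumentError("sound_speed must be positive")
        if not self.density > 0:
            raise InvalidArgumentError("density must be positive")


@dataclass(frozen=True)
class SlabShape:
    """Axis-aligned rectangular absorber, inclusive index bounds."""

    row_lo: int
    row_hi: int
    col_lo: int
    col_hi: int
    amplitude: float

    def rasterize(self, grid: Grid) -> np.ndarray:
        mask = np.zeros(grid.shape, dtype=bool)
        mask[self.row_lo : self.row_hi + 1, self.col_lo : self.col_hi + 1] = True
        return mask

    def thickness_mm(self, grid: Grid) -> float:
        return (self.row_hi - self.row_lo + 1) * grid.dx


@dataclass(frozen=True)
class DiscShape:
    """Circular absorber; center in physical mm, diameter in mm.

    A cell belongs to the disc iff its *center* lies within ``diameter/2``
    of the disc center.  The footprint area converges to pi*r^2 as the grid
    is refined.
    """

    center_y: float
    center_x: float
    diameter: float
    amplitude: float

    def rasterize(self, grid: Grid) -> np.ndarray:
        y, x = grid.cell_centers()
        dy = y[:, None] - self.center_y
        dxs = x[None, :] - self.center_x
        return dy * dy + dxs * dxs <= (self.diameter / 2.0) ** 2


@dataclass(frozen=True)
class Phantom:
    """Initial-pressure map plus the ledger of shapes that produced it."""

    grid: Grid
    p0: np.ndarray
    shapes: tuple = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        p0 = np.asarray(self.p0, dtype=float)
        if p0.shape != self.grid.shape:
            raise InvalidArgumentError("p0 shape does not match grid")
        if (p0 < 0).any():
            raise InvalidArgumentError("p0 must be non-negative")
        object.__setattr__(self, "p0", p0)

    def rasterize_ledger(self) -> np.ndarray:
        """Re-rasterize the shape ledger into a fresh p0 map."""
        out = np.zeros(self.grid.shape, dtype=float)
        for shape in self.shapes:
            out[shape.rasterize(self.grid)] = shape.amplitude
        return out

    @property
    def slabs(self) -> list[SlabShape]:
        return [s for s in self.shapes if isinstance(s, SlabShape)]

    @property
    def discs(self) -> list[DiscShape]:
        return [s for s in self.shapes if isinstance(s, DiscShape)]

    def slab_depth_bounds(self) -> tuple[float, float]:
        """Physical (top, bottom) Y bounds in mm of the first slab."""
        slabs = self.slabs
        if not slabs:
            raise InvalidArgumentError("phantom has no slab")
        s = slabs[0]
        return (s.row_lo * self.grid.dx, (s.row_hi + 1) * self.grid.dx)


def build_grid(n_rows: int, n_cols: int, dx: float) -> Grid:
    """Construct a grid; raises :class:`InvalidArgumentError` on bad input."""
    return Grid(n_rows=n_rows, n_cols=n_cols, dx=dx)


def new_phantom(grid: Grid) -> Phantom:
    """Empty phantom (p0 == 0 everywhere) on the given grid."""
    return Phantom(grid=grid, p0=np.zeros(grid.shape))


def add_slab(
    phantom: Phantom,
    row_lo: int,
    row_hi: int,
    col_lo: int,
    col_hi: int,
    amplitude: float,
) -> Phantom:
    """Return a new phantom with a uniform rectangular absorber added.

    Bounds are 0-based and inclusive.  The slab thickness is
    ``(row_hi - row_lo + 1) * dx``.
    """
    g = phantom.grid
    if not (0 <= row_lo <= row_hi < g.n_rows and 0 <= col_lo <= col_hi < g.n_cols):
        raise InvalidArgumentError("slab bounds outside grid or inverted")
    if not amplitude > 0:
        raise InvalidArgumentError("slab amplitude must be positive")
    shape = SlabShape(row_lo, row_hi, col_lo, col_hi, amplitude)
    p0 = phantom.p0.copy()
    p0[shape.rasterize(g)] = amplitude
    return replace(phantom, p0=p0, shapes=phantom.shapes + (shape,))


def scatter_discs(
    phantom: Phantom,
    n: int,
    diameter: float,
    seed: int,
    exclusion: Sequence[tuple[int, int, int, int]] = (),
    amplitude: float = 2.0,
    max_attempts_per_disc: int = 10_000,
) -> Phantom:
    """Add ``n`` disc absorbers at seeded uniform random positions.

    Placement is rejection sampling: a candidate center (drawn uniformly in
    mm over the region where the whole footprint fits inside the grid) is
    rejected if its footprint overlaps any slab already in the ledger or any
    exclusion rectangle (0-based inclusive ``(row_lo, row_hi, col_lo,
    col_hi)``).  Disc-disc overlap is allowed.  Deterministic given
    ``seed``.
    """
    if n < 0:
        raise InvalidArgumentError("n must be >= 0")
    if not diameter > 0:
        raise InvalidArgumentError("diameter must be positive")
    g = phantom.grid
    for rect in exclusion:
        r0, r1, c0, c1 = rect
        if not (0 <= r0 <= r1 < g.n_rows and 0 <= c0 <= c1 < g.n_cols):
            raise InvalidArgumentError(f"exclusion rectangle {rect} outside grid")
    if n == 0:
        return phantom

    forbidden = np.zeros(g.shape, dtype=bool)
    for s in phantom.slabs:
        forbidden |= s.rasterize(g)
    for r0, r1, c0, c1 in exclusion:
        forbidden[r0 : r1 + 1, c0 : c1 + 1] = True

    radius = diameter / 2.0
    lo_y, hi_y = radius, g.extent_y - radius
    lo_x, hi_x = radius, g.extent_x - radius
    if lo_y >= hi_y or lo_x >= hi_x:
        raise PlacementInfeasibleError("disc diameter exceeds the grid extent")

    rng = np.random.default_rng(seed)
    p0 = phantom.p0.copy()
    shapes = list(phantom.shapes)
    placed = 0
    attempts = 0
    budget = max_attempts_per_disc * n
    while placed < n:
        if attempts >= budget:
            raise PlacementInfeasibleError(
                f"placed only {placed}/{n} discs after {attempts} attempts"
            )
        attempts += 1
        cy = rng.uniform(lo_y, hi_y)
        cx = rng.uniform(lo_x, hi_x)
        disc = DiscShape(center_y=cy, center_x=cx, diameter=diameter, amplitude=amplitude)
        mask = disc.rasterize(g)
        if (mask & forbidden).any():
            continue
        p0[mask] = amplitude
        shapes.append(disc)
        placed += 1
    return replace(phantom, p0=p0, shapes=tuple(shapes), seed=seed)


def discrimination_phantom(seed: int) -> Phantom:
    """The reference slab-vs-discs discrimination scene.

    128 x 128 grid at 0.5 mm spacing; a 2 Pa slab spanning rows 58-68 and
    columns 23-103 (depth bounds 29.0-34.5 mm, thickness 5.5 mm, length
    40.5 mm); 30 discs of 2 mm diameter scattered at seeded random
    positions that avoid the slab footprint and the sensor row.
    """
    grid = build_grid(SIM_GRID_N, SIM_GRID_N, SIM_DX_MM)
    ph = new_phantom(grid)
    ph = add_slab(ph, SLAB_ROWS[0], SLAB_ROWS[1], SLAB_COLS[0], SLAB_COLS[1], 2.0)
    ph = scatter_discs(
        ph,
        n=30,
        diameter=2.0,
        seed=seed,
        exclusion=[(SENSOR_ROW, SENSOR_ROW, 0, SIM_GRID_N - 1)],
        amplitude=2.0,
    )
    return ph
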