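"""Parametric Cartesian grid and the tri-state vessel masking.

The grid is a uniform cubic-cell lattice described by three scalars only
(origin, spacing, counts); cell index <-> (i, j, k) is a pure function with
x-fastest linearization ``lin = i + nx*j + nx*ny*k``.  Masking classifies
every cell as extravascular (default), endothelial (cell center within
w/2 of a vessel surface) or interior (inside the lumen), by Euclidean
distance from the cell center to the finite centerline chord.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import OutOfBoundsError, ParameterError, ValidationError

EXTRAVASCULAR = 0
ENDOTHELIAL = 1
INTERIOR = 2


@dataclass(frozen=True)
class CartesianGrid:
    """Uniform cubic-cell grid: O(1) storage, derived everything else."""

    origin: tuple
    spacing: float
    shape: tuple  # (nx, ny, nz)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def cell_volume(self) -> float:
        return self.spacing**3

    @property
    def face_area(self) -> float:
        return self.spacing**2

    @property
    def bounds(self):
        lo = np.asarray(self.origin, float)
        hi = lo + self.spacing * np.asarray(self.shape, float)
        return lo, hi

    def cell_center(self, ijk) -> np.ndarray:
        ijk = np.asarray(ijk, float)
        return np.asarray(self.origin) + (ijk + 0.5) * self.spacing

    def point_to_index(self, points) -> np.ndarray:
        """(i, j, k) of the cell containing each point (clipped to the grid)."""
        p = np.atleast_2d(np.asarray(points, float))
        idx = np.floor((p - np.asarray(self.origin)) / self.spacing).astype(np.int64)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return idx[0] if np.asarray(points).ndim == 1 else idx

    def linear_index(self, ijk) -> np.ndarray:
        single = np.asarray(ijk).ndim == 1
        ijk = np.atleast_2d(np.asarray(ijk, np.int64))
        nx, ny, _ = self.shape
        lin = ijk[:, 0] + nx * ijk[:, 1] + nx * ny * ijk[:, 2]
        return lin[0] if single else lin

    def unravel(self, lin) -> np.ndarray:
        nx, ny, _ = self.shape
        lin = np.asarray(lin, np.int64)
        i = lin % nx
        j = (lin // nx) % ny
        k = lin // (nx * ny)
        return np.stack([i, j, k], axis=-1)

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.spacing


def build_grid(extents, spacing: float | None = None, shape=None,
               origin=(0.0, 0.0, 0.0)) -> CartesianGrid:
    """Build a cubic-cell grid covering a box of the given extents (µm).

    Give either ``spacing`` (cells are Δ³ cubes; the box is expanded
    symmetrically to the next multiple of Δ) or ``shape`` (counts per axis,
    which must imply a single cubic Δ).
    """
    extents = np.asarray(extents, float)
    if np.any(extents <= 0):
        raise ParameterError("box extents must be positive")
    if (spacing is None) == (shape is None):
        raise ParameterError("give exactly one of spacing or shape")
    if shape is not None:
        shape = tuple(int(c) for c in shape)
        deltas = extents / np.asarray(shape, float)
        if not np.allclose(deltas, deltas[0], rtol=1e-12, atol=0.0):
            raise ParameterError(
                f"cell counts {shape} imply non-cubic cells {deltas}; "
                "only cubic cells are supported"
            )
        return CartesianGrid(tuple(np.asarray(origin, float)), float(deltas[0]), shape)
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    counts = np.maximum(np.ceil(extents / spacing - 1e-12).astype(int), 2)
    # expand symmetrically to the next multiple of spacing
    new_origin = np.asarray(origin, float) - 0.5 * (counts * spacing - extents)
    return CartesianGrid(tuple(new_origin), float(spacing), tuple(int(c) for c in counts))


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

@dataclass
class VoxelLabels:
    """Result of masking a partitioned network onto a grid.

    ``label`` is an (nx, ny, nz) uint8 array over {EXTRAVASCULAR,
    ENDOTHELIAL, INTERIOR}.  ``endo_owner``/``interior_owner`` record the
    claiming segment per cell (−1 = none); ``interior_node`` the nearest
    vascular node of each lumen cell (for elimination by identity with the
    network unknown).  ``seg_endo_cells[s]`` lists the linear indices of the
    endothelial cells owned by segment ``s``; ``seg_area[s]`` the per-cell
    exchange area π·d·L/N; ``seg_fallback_cell[s]`` the single host cell of
    segments too small to claim any endothelial cell (−1 otherwise).
    """

    grid: CartesianGrid
    label: np.ndarray
    endo_owner: np.ndarray
    interior_owner: np.ndarray
    interior_node: np.ndarray
    seg_endo_cells: list
    seg_area: np.ndarray
    seg_fallback_cell: np.ndarray
    endothelial_thickness: float = 1.0

    @property
    def n_interior(self) -> int:
        return int(np.count_nonzero(self.label == INTERIOR))

    @property
    def n_endothelial(self) -> int:
        return int(np.count_nonzero(self.label == ENDOTHELIAL))

    @property
    def n_extravascular(self) -> int:
        return int(np.count_nonzero(self.label == EXTRAVASCULAR))

    @property
    def tissue_cells(self) -> np.ndarray:
        """Linear indices of the non-lumen (endothelial + extravascular) cells."""
        flat = self.label.reshape(-1, order="F")
        return np.flatnonzero(flat != INTERIOR)


def _chord_distance(centers: np.ndarray, p0: np.ndarray, p1: np.ndarray):
    """Distance from points to the finite chord p0–p1 (flat caps) and the
    clamped parameter t of the closest point."""
    axis = p1 - p0
    L2 = float(axis @ axis)
    rel = centers - p0
    t = np.clip(rel @ axis / L2, 0.0, 1.0) if L2 > 0 else np.zeros(len(rel))
    closest = p0 + t[:, None] * axis
    return np.linalg.norm(centers - closest, axis=1), t


def segment_claims(d: float, dist: np.ndarray, w: float):
    """Per-cell claim of one segment: endothelial if |dist − r| ≤ w/2,
    else interior if dist < r.  Returns (endo_mask, interior_mask)."""
    r = 0.5 * d
    endo = np.abs(dist - r) <= 0.5 * w
    interior = ~endo & (dist < r)
    return endo, interior


def label_mesh(grid: CartesianGrid, net, w: float = 1.0) -> VoxelLabels:
    """Classify every grid cell against a partitioned network.

    For each non-occluded segment the candidate cells are those whose
    centers lie in the chord's bounding box expanded by r + w/2 (the
    expansion cannot change labels, only the candidate set).  Label
    priority across overlapping segments is INTERIOR > ENDOTHELIAL >
    EXTRAVASCULAR; shared endothelial cells are owned by the segment of
    minimal |dist − r| (ties: lowest segment index).  Each segment's
    lateral surface π·d·L is split evenly among its endothelial cells.
    Segments that claim no cell at all couple to the single cell
    containing their midpoint.
    """
    lo, hi = grid.bounds
    xyz = net.node_xyz
    heads = xyz[net.seg_head]
    tails = xyz[net.seg_tail]
    if np.any(heads < lo - 1e-9) or np.any(heads > hi + 1e-9) or \
       np.any(tails < lo - 1e-9) or np.any(tails > hi + 1e-9):
        bad = np.flatnonzero(
            np.any((heads < lo - 1e-9) | (heads > hi + 1e-9), axis=1)
            | np.any((tails < lo - 1e-9) | (tails > hi + 1e-9), axis=1)
        )
        raise OutOfBoundsError(f"segments outside grid: {bad.tolist()}")

    n_cells = grid.n_cells
    nx, ny, nz = grid.shape
    label = np.zeros(n_cells, dtype=np.uint8)
    endo_metric = np.full(n_cells, np.inf)
    endo_owner = np.full(n_cells, -1, dtype=np.int64)
    int_metric = np.full(n_cells, np.inf)
    int_owner = np.full(n_cells, -1, dtype=np.int64)

    origin = np.asarray(grid.origin)
    delta = grid.spacing

    for s in range(net.n_segments):
        if net.occluded[s] or net.diameter[s] <= 0:
            continue
        p0, p1 = heads[s], tails[s]
        r = 0.5 * net.diameter[s]
        pad = r + 0.5 * w
        blo = np.minimum(p0, p1) - pad
        bhi = np.maximum(p0, p1) + pad
        # cells whose centers lie inside [blo, bhi]
        i0 = np.maximum(np.ceil((blo - origin) / delta - 0.5).astype(int), 0)
        i1 = np.minimum(np.floor((bhi - origin) / delta - 0.5).astype(int),
                        np.asarray(grid.shape) - 1)
        if np.any(i1 < i0):
            continue
        ii, jj, kk = np.meshgrid(
            np.arange(i0[0], i1[0] + 1),
            np.arange(i0[1], i1[1] + 1),
            np.arange(i0[2], i1[2] + 1),
            indexing="ij",
        )
        ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        centers = origin + (ijk + 0.5) * delta
        dist, _ = _chord_distance(centers, p0, p1)
        endo, inter = segment_claims(net.diameter[s], dist, w)
        lin = ijk[:, 0] + nx * ijk[:, 1] + nx * ny * ijk[:, 2]

        if np.any(endo):
            le, me = lin[endo], np.abs(dist[endo] - r)
            take = me < endo_metric[le]
            endo_metric[le[take]] = me[take]
            endo_owner[le[take]] = s
        if np.any(inter):
            li, mi = lin[inter], dist[inter]
            take = mi < int_metric[li]
            int_metric[li[take]] = mi[take]
            int_owner[li[take]] = s

    label[endo_owner >= 0] = ENDOTHELIAL
    label[int_owner >= 0] = INTERIOR  # interior has priority

    # nearest vascular node of each interior cell: nearer endpoint of the
    # owning segment (ties -> head)
    interior_node = np.full(n_cells, -1, dtype=np.int64)
    lumen = np.flatnonzero(label == INTERIOR)
    if lumen.size:
        ijk = grid.unravel(lumen)
        centers = origin + (ijk + 0.5) * delta
        own = int_owner[lumen]
        dh = np.linalg.norm(centers - heads[own], axis=1)
        dt = np.linalg.norm(centers - tails[own], axis=1)
        interior_node[lumen] = np.where(dt < dh, net.seg_tail[own], net.seg_head[own])

    # per-segment endothelial cell lists (final labels only)
    endo_cells = np.flatnonzero(label == ENDOTHELIAL)
    seg_endo_cells = [np.empty(0, dtype=np.int64) for _ in range(net.n_segments)]
    if endo_cells.size:
        owners = endo_owner[endo_cells]
        order = np.argsort(owners, kind="stable")
        sorted_cells = endo_cells[order]
        sorted_owners = owners[order]
        starts = np.searchsorted(sorted_owners, np.arange(net.n_segments))
        ends = np.searchsorted(sorted_owners, np.arange(net.n_segments), side="right")
        for s in range(net.n_segments):
            if ends[s] > starts[s]:
                seg_endo_cells[s] = sorted_cells[starts[s]:ends[s]]

    lengths = net.lengths
    seg_area = np.zeros(net.n_segments)
    seg_fallback = np.full(net.n_segments, -1, dtype=np.int64)
    flat_label = label  # linear order
    for s in range(net.n_segments):
        if net.occluded[s] or net.diameter[s] <= 0:
            continue
        n_endo = seg_endo_cells[s].size
        surface = np.pi * net.diameter[s] * lengths[s]
        if n_endo:
            seg_area[s] = surface / n_endo
        else:
            mid = 0.5 * (heads[s] + tails[s])
            host = int(grid.linear_index(grid.point_to_index(mid)))
            if flat_label[host] == INTERIOR:
                host = _nearest_non_interior(grid, flat_label, host)
            seg_fallback[s] = host
            seg_area[s] = surface

    return VoxelLabels(
        grid=grid,
        label=label.reshape((nx, ny, nz), order="F"),
        endo_owner=endo_owner,
        interior_owner=int_owner,
        interior_node=interior_node,
        seg_endo_cells=seg_endo_cells,
        seg_area=seg_area,
        seg_fallback_cell=seg_fallback,
        endothelial_thickness=w,
    )


def _nearest_non_interior(grid: CartesianGrid, flat_label, host: int) -> int:
    """Expanding Chebyshev-shell search for the closest non-lumen cell."""
    nx, ny, nz = grid.shape
    i0, j0, k0 = grid.unravel(host)
    for radius in range(1, max(grid.shape)):
        best = -1
        best_d = np.inf
        for di in range(-radius, radius + 1):
            for dj in range(-radius, radius + 1):
                for dk in range(-radius, radius + 1):
                    if max(abs(di), abs(dj), abs(dk)) != radius:
                        continue
                    i, j, k = i0 + di, j0 + dj, k0 + dk
                    if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
                        continue
                    lin = i + nx * j + nx * ny * k
                    if flat_label[lin] != INTERIOR:
                        d = di * di + dj * dj + dk * dk
                        if d < best_d:
                            best_d, best = d, lin
        if best >= 0:
            return best
    raise ValidationError("grid contains no non-lumen cell for fallback coupling")


def build_hierarchy(grid: CartesianGrid, levels: int, factor: int = 2):
    """Coarse-to-fine list of grids over the same box (Δ scaled by factor).

    The finest grid's counts must be divisible by factor**(levels−1).
    Labels are recomputed per level by the caller, never downsampled.
    """
    if levels < 1:
        raise ParameterError("levels must be >= 1")
    grids = []
    for lvl in range(levels - 1, -1, -1):
        f = factor**lvl
        if any(c % f for c in grid.shape):
            raise ParameterError(
                f"grid shape {grid.shape} not divisible by {f} for level {lvl}"
            )
        grids.append(
            CartesianGrid(grid.origin, grid.spacing * f,
                          tuple(c // f for c in grid.shape))
        )
    return grids
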