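"""Sparse linear solvers and the coarse-to-fine multiscale strategy.

The coupled oxygen system is solved with restarted GMRES and an ILU or
block-Jacobi preconditioner.  The returned residual is always recomputed
independently of the iterative method's internal estimate, and a solve
never silently returns an unconverged iterate.  Multiscale initialization
solves the same physics on a hierarchy of grids, trilinearly interpolating
each coarse tissue field down as the next level's starting guess — it
changes the path to the solution, never the converged answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .errors import NonConvergenceError, ParameterError, SolverError
from .oxygen import (
    OxygenSolution,
    PhysiologyParams,
    TransportSystem,
    assemble_coupled_system,
    split_solution,
)
from .voxels import INTERIOR, CartesianGrid, label_mesh


@dataclass
class ConvergenceRecord:
    iterations: int
    residual: float          # true relative residual ||b - Ax|| / ||b||
    history: list = field(default_factory=list)
    preconditioner: str = "ilu"


def _scaled_ilu(A: sp.spmatrix):
    """ILU of the row-equilibrated matrix (scaling avoids zero pivots when
    convection, exchange and reaction rows differ by orders of magnitude)."""
    d = np.abs(A.diagonal())
    d[d == 0] = 1.0
    inv = 1.0 / d
    As = (sp.diags(inv) @ A).tocsc()
    try:
        ilu = spla.spilu(As, drop_tol=1e-5, fill_factor=10.0)
    except RuntimeError:
        ilu = spla.splu(As)  # small systems: fall back to a complete factor

    def solve(x):
        return ilu.solve(inv * x)

    return solve


def _make_preconditioner(A: sp.csr_matrix, kind: str, block_split: int | None):
    if kind == "none":
        return None
    if kind == "ilu":
        return spla.LinearOperator(A.shape, _scaled_ilu(A))
    if kind == "block_jacobi":
        # two natural blocks: vascular unknowns, tissue unknowns
        n = A.shape[0]
        split = block_split if block_split is not None else n // 2
        solve1 = _scaled_ilu(A[:split, :split].tocsr()) if split else None
        solve2 = _scaled_ilu(A[split:, split:].tocsr()) if n - split else None

        def apply(x):
            y = np.empty_like(x)
            if solve1 is not None:
                y[:split] = solve1(x[:split])
            if solve2 is not None:
                y[split:] = solve2(x[split:])
            return y

        return spla.LinearOperator(A.shape, apply)
    raise ParameterError(f"unknown preconditioner {kind!r}")


def solve_sparse(
    A: sp.spmatrix,
    b: np.ndarray,
    rtol: float = 1e-10,
    max_iter: int | None = None,
    preconditioner: str = "ilu",
    x0: np.ndarray | None = None,
    restart: int = 200,
    block_split: int | None = None,
):
    """Solve A x = b to a true relative residual ≤ rtol.

    GMRES with the requested preconditioner; the residual is recomputed
    from A and b after every pass, and a few iterative-refinement passes
    polish the iterate when GMRES's internal estimate is optimistic.
    Raises :class:`NonConvergenceError` (with the residual history) instead
    of returning an unconverged x.
    """
    A = A.tocsr()
    if A.shape[0] != A.shape[1]:
        raise SolverError("system must be square")
    b = np.asarray(b, float)
    if not np.all(np.isfinite(b)):
        raise SolverError("right-hand side contains non-finite values")

    # row equilibration: convection, exchange and reaction rows differ by
    # many orders of magnitude, so residuals are driven to rtol in the
    # equilibrated norm ||D(b − Ax)|| / ||Db||, D = diag(1 / max|row|)
    rmax = np.ones(A.shape[0])
    nnz_rows = np.diff(A.indptr) > 0
    if A.nnz:
        rm = np.maximum.reduceat(np.abs(A.data), A.indptr[:-1][nnz_rows])
        rmax[nnz_rows] = np.where(rm > 0, rm, 1.0)
    D = sp.diags(1.0 / rmax)
    A = (D @ A).tocsr()
    b = b / rmax

    norm_b = np.linalg.norm(b)
    if norm_b == 0:
        return np.zeros_like(b), ConvergenceRecord(0, 0.0, [], preconditioner)
    if max_iter is None:
        max_iter = 10 * restart

    M = _make_preconditioner(A, preconditioner, block_split)
    history: list = []
    iters = [0]

    def callback(pr_norm):
        iters[0] += 1
        history.append(float(pr_norm))

    x = x0.copy() if x0 is not None else np.zeros_like(b)
    # outer iterative-refinement loop around restarted GMRES
    for _ in range(8):
        res = b - A @ x
        rel = np.linalg.norm(res) / norm_b
        history.append(float(rel))
        if rel <= rtol:
            return x, ConvergenceRecord(iters[0], rel, history, preconditioner)
        dx, _info = spla.gmres(
            A,
            res,
            rtol=max(rtol / max(rel, 1e-300) * 0.1, 1e-14),
            atol=0.0,
            restart=restart,
            maxiter=max(1, max_iter // restart),  # restart cycles
            M=M,
            callback=callback,
            callback_type="pr_norm",
        )
        x = x + dx
    res = b - A @ x
    rel = np.linalg.norm(res) / norm_b
    if rel <= rtol:
        return x, ConvergenceRecord(iters[0], rel, history, preconditioner)
    raise NonConvergenceError(
        f"GMRES stagnated at relative residual {rel:.3e} (target {rtol:.1e})",
        history=history,
    )


# ---------------------------------------------------------------------------
# Multiscale
# ---------------------------------------------------------------------------

def _filled_field(solution: OxygenSolution) -> np.ndarray:
    """Coarse tissue field with lumen cells replaced by the nearest coupled
    (non-lumen) cell's value, ready for trilinear interpolation."""
    grid = solution.system.grid
    labels = solution.system.labels
    flat = np.zeros(grid.n_cells)
    flat[solution.system.tissue_cells] = solution.ct
    nx, ny, nz = grid.shape
    arr = flat.reshape((nx, ny, nz), order="F")
    lumen = labels.label == INTERIOR
    if np.any(lumen):
        _, idx = ndimage.distance_transform_edt(lumen, return_indices=True)
        arr = arr[tuple(idx)]
    return arr


def interpolate_field(coarse_grid: CartesianGrid, coarse: np.ndarray,
                      points: np.ndarray) -> np.ndarray:
    """Trilinear sample of a cell-centered coarse field at arbitrary points."""
    frac = (points - np.asarray(coarse_grid.origin)) / coarse_grid.spacing - 0.5
    return ndimage.map_coordinates(coarse, frac.T, order=1, mode="nearest")


def multiscale_solve(
    net,
    grid_hierarchy,
    flow,
    params: PhysiologyParams,
    bc,
    rtol: float = 1e-10,
    w: float | None = None,
    preconditioner: str = "ilu",
    restart: int = 200,
) -> OxygenSolution:
    """Coarse-to-fine solve of the coupled oxygen problem.

    The network must already be partitioned for the *finest* grid (the
    span-two-voxels criterion then holds a fortiori on every coarser one),
    so the vascular unknowns are identical across levels: cv carries over
    directly, ct is trilinearly interpolated.  Tissue Dirichlet cells (keyed
    on the finest grid) are applied at the finest level only.
    """
    if not grid_hierarchy:
        raise ParameterError("empty grid hierarchy")
    w = params.w if w is None else w
    x = None
    prev_solution = None
    records = []
    finest = grid_hierarchy[-1]
    for grid in grid_hierarchy:
        level_bc = bc if grid is finest else _without_tissue_dirichlet(bc)
        labels = label_mesh(grid, net, w=w)
        system = assemble_coupled_system(net, grid, labels, flow.f, flow.h,
                                         params, level_bc)
        if prev_solution is not None:
            coarse_field = _filled_field(prev_solution)
            centers = (
                np.asarray(grid.origin)
                + (grid.unravel(system.tissue_cells) + 0.5) * grid.spacing
            )
            ct0 = interpolate_field(prev_solution.system.grid, coarse_field, centers)
            x0 = np.concatenate([prev_solution.cv, ct0])
        else:
            x0 = None
        try:
            x, rec = solve_sparse(
                system.A, system.b, rtol=rtol, preconditioner=preconditioner,
                x0=x0, restart=restart, block_split=system.n_vascular,
            )
        except NonConvergenceError as err:
            raise NonConvergenceError(
                f"multiscale level with shape {grid.shape} failed: {err}",
                history=err.history,
            ) from err
        records.append(rec)
        prev_solution = split_solution(system, x, rec.iterations, rec.residual)
    prev_solution.level_records = records
    prev_solution.iterations = sum(r.iterations for r in records)
    prev_solution.residual = records[-1].residual
    return prev_solution


def _without_tissue_dirichlet(bc):
    out = bc.copy()
    out.tissue_dirichlet = {}
    return out


def solve_oxygen(
    net,
    grid: CartesianGrid,
    flow,
    params: PhysiologyParams,
    bc,
    rtol: float = 1e-10,
    levels: int = 1,
    factor: int = 2,
    preconditioner: str = "ilu",
) -> OxygenSolution:
    """Convenience wrapper: build the hierarchy and run the multiscale solve."""
    from .voxels import build_hierarchy

    hierarchy = build_hierarchy(grid, levels, factor)
    return multiscale_solve(net, hierarchy, flow, params, bc, rtol=rtol,
                            preconditioner=preconditioner)
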