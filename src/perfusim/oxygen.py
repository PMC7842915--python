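"""Coupled vascular–tissue oxygen transport on the masked Cartesian grid.

The steady oxygen tension (pO2, mmHg) is solved simultaneously for the
vascular network nodes (cv) and the non-lumen grid cells (ct).  The blocks:

* ``Mc``   — upwinded convection through the network, weighted by the RBC
  carrying capacity β(h) (default β = h/h_ref so convected oxygen follows
  the red-cell flux; β ≡ 1 is available);
* ``C3ᵀΓ1C3`` — transmembrane exchange between a segment's endpoint nodes
  and its endothelial cells, conductance U·A_cell/w per coupling;
* ``Md``   — 7-point finite-volume diffusion over endothelial and
  extravascular cells (zero flux to the lumen and the domain exterior);
* ``R2``   — first-order metabolic consumption k_met·ct·Vt in every tissue
  cell.

Interior lumen cells never appear as unknowns: they are eliminated by
identity with the nearest vascular node and reconstructed afterwards.
Intravascular diffusion is neglected (axial Peclet >> 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ParameterError, SolverError, ValidationError
from .network import BoundaryConditionSet, VascularNetwork
from .voxels import ENDOTHELIAL, EXTRAVASCULAR, INTERIOR, CartesianGrid, VoxelLabels


@dataclass
class PhysiologyParams:
    """Physiological constants of the oxygen problem.

    D: tissue diffusivity (µm²/s); U: transmembrane permeability (µm²/s);
    w: endothelial thickness (µm); k_met: first-order CMRO2 rate (1/s —
    use :meth:`from_per_ms` for the 1/ms convention); inlet_oxygen:
    arterial inlet tension (mmHg); alpha: optional solubility
    (amount / (µm³·mmHg)) used only to report molar fluxes; beta_model:
    'rbc' scales convected oxygen by h/h_ref, 'unit' convects the bare
    tension; h_ref: reference (systemic) hematocrit for β.
    """

    D: float = 1800.0
    U: float = 2400.0
    w: float = 1.0
    k_met: float = 14.17e3  # 14.17 per ms
    inlet_oxygen: float = 68.5
    alpha: float | None = None
    beta_model: str = "rbc"
    h_ref: float = 0.35

    @classmethod
    def from_per_ms(cls, k_met_per_ms: float = 14.17, **kw) -> "PhysiologyParams":
        return cls(k_met=k_met_per_ms * 1e3, **kw)

    def validate(self) -> None:
        for name in ("D", "U", "w", "inlet_oxygen", "h_ref"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.k_met < 0:
            raise ParameterError("k_met must be nonnegative")
        if self.beta_model not in ("rbc", "unit"):
            raise ParameterError(f"unknown beta_model {self.beta_model!r}")

    def beta(self, h) -> np.ndarray:
        """Carrying-capacity factor multiplying the convective flux."""
        if self.beta_model == "unit":
            return np.ones_like(np.asarray(h, float))
        return np.asarray(h, float) / self.h_ref


def effective_flux(f, h, params: PhysiologyParams) -> np.ndarray:
    """Oxygen-carrying volumetric flux φ = f · β(h) per segment."""
    return np.asarray(f, float) * params.beta(h)


# ---------------------------------------------------------------------------
# Block assembly
# ---------------------------------------------------------------------------

def assemble_convection(net: VascularNetwork, f, h,
                        params: PhysiologyParams | None = None) -> sp.csr_matrix:
    """Upwinded vascular convection operator Mc (nPts × nPts).

    Row n balances node n: inflowing flux φ·cv_upwind enters, the total
    inflow leaves (through downstream segments or the boundary), so row
    sums vanish at every node — boundary outflow is implicit in the
    diagonal.  Asymmetric whenever any flow is nonzero.
    """
    params = params or PhysiologyParams()
    f = np.asarray(f, float)
    if not np.all(np.isfinite(f)):
        raise ValidationError("flow field contains non-finite values")
    phi = np.abs(effective_flux(f, h, params))
    up = np.where(f >= 0, net.seg_head, net.seg_tail)
    dn = np.where(f >= 0, net.seg_tail, net.seg_head)
    keep = phi > 0
    n = net.n_nodes
    inflow = np.zeros(n)
    np.add.at(inflow, dn[keep], phi[keep])
    rows = np.r_[dn[keep], np.flatnonzero(inflow > 0)]
    cols = np.r_[up[keep], np.flatnonzero(inflow > 0)]
    vals = np.r_[phi[keep], -inflow[inflow > 0]]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def tissue_index_map(labels: VoxelLabels):
    """Compressed row index for every non-lumen cell (−1 for lumen)."""
    flat = labels.label.reshape(-1, order="F")
    tissue = np.flatnonzero(flat != INTERIOR)
    index = np.full(flat.size, -1, dtype=np.int64)
    index[tissue] = np.arange(tissue.size)
    return tissue, index


def mass_transfer_couplings(net: VascularNetwork, labels: VoxelLabels,
                            params: PhysiologyParams, exclude_nodes=()):
    """(node, linear cell, conductance) triplets of the exchange couplings.

    Each endothelial cell couples to the nearer endpoint of its owning
    segment (ties to the head) with conductance U·A_cell/w, A_cell being
    the even split π·d·L/N of the segment surface.  Segments with no
    endothelial cell couple their full surface to the fallback host cell.
    ``exclude_nodes`` (the oxygen Dirichlet inlets) never receive a
    coupling — it moves to the segment's other endpoint, so that the global
    balance "inlet feed = outlet flux + transfer" closes exactly.
    """
    excl = set(int(v) for v in exclude_nodes)
    nodes, cells, conds = [], [], []
    xyz = net.node_xyz
    origin = np.asarray(labels.grid.origin)
    delta = labels.grid.spacing

    def _endpoint(s, prefer_tail):
        a = int(net.seg_tail[s]) if prefer_tail else int(net.seg_head[s])
        b = int(net.seg_head[s]) if prefer_tail else int(net.seg_tail[s])
        if a in excl and b not in excl:
            return b
        return a

    for s in range(net.n_segments):
        if net.occluded[s] or net.diameter[s] <= 0:
            continue
        ec = labels.seg_endo_cells[s]
        g = params.U * labels.seg_area[s] / params.w
        if ec.size:
            centers = origin + (labels.grid.unravel(ec) + 0.5) * delta
            dh = np.linalg.norm(centers - xyz[net.seg_head[s]], axis=1)
            dt = np.linalg.norm(centers - xyz[net.seg_tail[s]], axis=1)
            owner = [_endpoint(s, bool(pt)) for pt in (dt < dh)]
            nodes.extend(owner)
            cells.extend(ec.tolist())
            conds.extend([g] * ec.size)
        elif labels.seg_fallback_cell[s] >= 0:
            nodes.append(_endpoint(s, False))
            cells.append(int(labels.seg_fallback_cell[s]))
            conds.append(g)
        else:
            raise ValidationError(
                f"segment {s} has no coupled cell: labeling contract violated"
            )
    return (
        np.asarray(nodes, dtype=np.int64),
        np.asarray(cells, dtype=np.int64),
        np.asarray(conds, dtype=float),
    )


def assemble_mass_transfer(net: VascularNetwork, labels: VoxelLabels,
                           params: PhysiologyParams, exclude_nodes=()):
    """Coupling incidence C3 (nCouplings × (nPts + nTissue)) and diagonal Γ1.

    ``C3ᵀ Γ1 C3`` is the symmetric exchange Laplacian of the bipartite
    node–cell coupling graph.
    """
    node, cell, g = mass_transfer_couplings(net, labels, params, exclude_nodes)
    tissue, index = tissue_index_map(labels)
    n_v = net.n_nodes
    n_t = tissue.size
    nc = node.size
    crow = index[cell]
    if np.any(crow < 0):
        raise ValidationError("coupling targets a lumen cell")
    rows = np.repeat(np.arange(nc), 2)
    cols = np.empty(2 * nc, dtype=np.int64)
    cols[0::2] = node
    cols[1::2] = n_v + crow
    vals = np.tile([1.0, -1.0], nc)
    C3 = sp.csr_matrix((vals, (rows, cols)), shape=(nc, n_v + n_t))
    Gamma1 = sp.diags(g)
    return C3, Gamma1


def assemble_diffusion(grid: CartesianGrid, labels: VoxelLabels, D: float) -> sp.csr_matrix:
    """7-point finite-volume Laplacian over non-lumen cells.

    Face conductance between adjacent coupled cells is D·Δ²/Δ = D·Δ; faces
    to lumen cells and to the domain exterior carry zero flux.  Symmetric,
    rows sum to zero.
    """
    tissue, index = tissue_index_map(labels)
    nx, ny, nz = grid.shape
    lab = labels.label  # (nx, ny, nz)
    ok = lab != INTERIOR
    cond = D * grid.spacing
    rows, cols = [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        pair = ok[tuple(sl_a)] & ok[tuple(sl_b)]
        ia, ja, ka = np.nonzero(pair)
        shift = np.zeros(3, dtype=np.int64)
        shift[axis] = 1
        lin_a = ia + nx * ja + nx * ny * ka
        lin_b = (ia + shift[0]) + nx * (ja + shift[1]) + nx * ny * (ka + shift[2])
        rows.append(index[lin_a])
        cols.append(index[lin_b])
    if rows:
        ra = np.concatenate(rows)
        ca = np.concatenate(cols)
    else:
        ra = ca = np.empty(0, np.int64)
    n_t = tissue.size
    vals = np.full(ra.size, cond)
    off = sp.coo_matrix(
        (np.r_[vals, vals], (np.r_[ra, ca], np.r_[ca, ra])), shape=(n_t, n_t)
    ).tocsr()
    diag = np.asarray(off.sum(axis=1)).ravel()
    return (off - sp.diags(diag)).tocsr()


def assemble_reaction(grid: CartesianGrid, labels: VoxelLabels, k_met: float) -> sp.csr_matrix:
    """Diagonal metabolic sink R2 = k_met · Vt on every non-lumen cell."""
    if k_met < 0:
        raise ParameterError("k_met must be nonnegative")
    tissue, _ = tissue_index_map(labels)
    return sp.diags(np.full(tissue.size, k_met * grid.cell_volume)).tocsr()


# ---------------------------------------------------------------------------
# Coupled system
# ---------------------------------------------------------------------------

@dataclass
class TransportSystem:
    """Assembled sparse coupled oxygen system and its audit bookkeeping."""

    A: sp.csr_matrix
    b: np.ndarray
    n_vascular: int
    tissue_cells: np.ndarray      # linear cell index per tissue row
    grid: CartesianGrid
    labels: VoxelLabels
    Mc: sp.csr_matrix
    Md: sp.csr_matrix
    R2: sp.csr_matrix
    exchange: sp.csr_matrix       # C3ᵀ Γ1 C3
    couplings: tuple              # (node, linear cell, conductance)
    inlet_nodes: np.ndarray
    inlet_flux: np.ndarray        # effective RBC-weighted inflow per inlet
    outlet_nodes: np.ndarray
    outlet_flux: np.ndarray       # effective exit flux coefficient per outlet
    dirichlet_rows: np.ndarray
    params: PhysiologyParams = field(default=None)

    @property
    def n_unknowns(self) -> int:
        return self.A.shape[0]


@dataclass
class OxygenSolution:
    """Converged oxygen tensions plus solver provenance."""

    cv: np.ndarray                # per vascular node, mmHg
    ct: np.ndarray                # per tissue row, mmHg
    system: TransportSystem
    iterations: int = 0
    residual: float = 0.0
    level_records: list = field(default_factory=list)

    def reconstructed_field(self) -> np.ndarray:
        """Full (nx, ny, nz) pO2 field; lumen cells take their node's cv."""
        grid = self.system.grid
        labels = self.system.labels
        flat = np.zeros(grid.n_cells)
        flat[self.system.tissue_cells] = self.ct
        lumen = np.flatnonzero(labels.label.reshape(-1, order="F") == INTERIOR)
        if lumen.size:
            flat[lumen] = self.cv[labels.interior_node[lumen]]
        nx, ny, nz = grid.shape
        return flat.reshape((nx, ny, nz), order="F")


def assemble_coupled_system(
    net: VascularNetwork,
    grid: CartesianGrid,
    labels: VoxelLabels,
    f,
    h,
    params: PhysiologyParams,
    bc: BoundaryConditionSet,
) -> TransportSystem:
    """Concatenate all blocks into the reduced square system.

    Unknowns: nPts vascular nodes, then the non-lumen cells.  Vascular
    Dirichlet rows (oxygen inlets: nodes where effective flux enters the
    domain) and tissue Dirichlet rows are replaced by identity rows with
    the boundary value on the right-hand side.
    """
    params.validate()
    tissue, index = tissue_index_map(labels)
    n_v, n_t = net.n_nodes, tissue.size

    # effective boundary throughput per node -> oxygen Dirichlet inlets
    phi = effective_flux(f, h, params)
    up = np.where(np.asarray(f) >= 0, net.seg_head, net.seg_tail)
    dn = np.where(np.asarray(f) >= 0, net.seg_tail, net.seg_head)
    net_out = np.zeros(n_v)
    np.add.at(net_out, up, np.abs(phi))
    np.add.at(net_out, dn, -np.abs(phi))
    scale = np.max(np.abs(phi)) if phi.size else 0.0
    inlet_nodes = np.flatnonzero(net_out > 1e-9 * scale)
    outlet_nodes = np.flatnonzero(net_out < -1e-9 * scale)

    Mc = assemble_convection(net, f, h, params)
    C3, Gamma1 = assemble_mass_transfer(net, labels, params,
                                        exclude_nodes=inlet_nodes)
    Md = assemble_diffusion(grid, labels, params.D)
    R2 = assemble_reaction(grid, labels, params.k_met)

    exchange = (C3.T @ Gamma1 @ C3).tocsr()
    A = sp.block_diag([Mc, Md], format="csr") - exchange
    A = A - sp.block_diag([sp.csr_matrix((n_v, n_v)), R2], format="csr")

    b = np.zeros(n_v + n_t)
    dirichlet = np.zeros(n_v + n_t, bool)

    missing = [int(v) for v in inlet_nodes if v not in bc.inlet_oxygen]
    if missing:
        raise SolverError(
            f"perfused inlets without oxygen boundary values: nodes {missing}"
        )

    A = A.tolil()
    for v in inlet_nodes:
        A.rows[v] = [int(v)]
        A.data[v] = [1.0]
        b[v] = bc.inlet_oxygen[int(v)]
        dirichlet[v] = True
    for lin_cell, val in bc.tissue_dirichlet.items():
        row = index[int(lin_cell)]
        if row < 0:
            continue  # Dirichlet requested on a lumen cell: eliminated anyway
        r = n_v + int(row)
        A.rows[r] = [r]
        A.data[r] = [1.0]
        b[r] = float(val)
        dirichlet[r] = True
    A = A.tocsr()

    # guard truly empty rows (stagnant, uncoupled vascular nodes)
    row_nnz = np.diff(A.indptr)
    empty = np.flatnonzero(row_nnz == 0)
    if empty.size:
        A = A.tolil()
        for r in empty:
            A.rows[r] = [int(r)]
            A.data[r] = [1.0]
            b[r] = 0.0
        A = A.tocsr()

    node_c, cell_c, g_c = mass_transfer_couplings(net, labels, params,
                                                  exclude_nodes=inlet_nodes)
    return TransportSystem(
        A=A,
        b=b,
        n_vascular=n_v,
        tissue_cells=tissue,
        grid=grid,
        labels=labels,
        Mc=Mc,
        Md=Md,
        R2=R2,
        exchange=exchange,
        couplings=(node_c, cell_c, g_c),
        inlet_nodes=inlet_nodes,
        inlet_flux=net_out[inlet_nodes],
        outlet_nodes=outlet_nodes,
        outlet_flux=-net_out[outlet_nodes],
        dirichlet_rows=dirichlet,
        params=params,
    )


def split_solution(system: TransportSystem, x: np.ndarray,
                   iterations: int = 0, residual: float = 0.0) -> OxygenSolution:
    n_v = system.n_vascular
    return OxygenSolution(
        cv=x[:n_v].copy(),
        ct=x[n_v:].copy(),
        system=system,
        iterations=iterations,
        residual=residual,
    )
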