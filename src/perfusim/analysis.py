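"""Downstream quantification: conservation audits, raytracing, depth maps,
hypoxic fractions, coarse-averaged comparison maps, ROI extraction, and the
in-silico aging perturbations (capillary micro-occlusions and systemic
hematocrit reduction)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AuditError, ParameterError
from .hemodynamics import FlowAudit
from .network import BoundaryConditionSet, VascularNetwork
from .oxygen import OxygenSolution, TransportSystem
from .solvers import interpolate_field
from .voxels import INTERIOR, CartesianGrid

#: default hypoxia thresholds: severe / mild / moderate pO2 cutoffs (mmHg)
HYPOXIA_THRESHOLDS = (5.0, 10.0, 15.0)
#: default cortical observation depths (µm below the pial surface)
DEPTH_PLANES = (120.0, 280.0, 480.0, 680.0, 880.0)


@dataclass
class MassAudit:
    """Divergence audit for the coupled run (blood + oxygen sections).

    Fluxes are in tension-volume units (mmHg·µm³/s) unless a solubility
    α is configured, in which case molar values α·flux are also exposed.
    """

    flow: FlowAudit
    oxygen_inlet: float
    oxygen_outlet: float
    oxygen_transfer: float
    oxygen_loss_percent: float
    max_balance_error_percent: float

    def as_dict(self) -> dict:
        return {
            "blood_inflow_nl_per_s": self.flow.inflow_nl_per_s,
            "blood_outflow_nl_per_s": self.flow.outflow_nl_per_s,
            "blood_loss_percent": self.flow.loss_percent,
            "blood_max_imbalance_percent": self.flow.max_imbalance_percent,
            "oxygen_inlet": self.oxygen_inlet,
            "oxygen_outlet": self.oxygen_outlet,
            "oxygen_transfer": self.oxygen_transfer,
            "oxygen_loss_percent": self.oxygen_loss_percent,
            "oxygen_max_balance_error_percent": self.max_balance_error_percent,
        }


def oxygen_mass_audit(system: TransportSystem, solution: OxygenSolution,
                      flow_audit: FlowAudit | None = None) -> MassAudit:
    """Recompute the oxygen balance from the raw blocks (not the solver).

    inlet feed = Σ inlet effective flux · c̄v; outlet flux = Σ outlet
    effective flux · cv; transfer = Σ couplings g (cv − ct).  The normalized
    loss |in − out − transfer| / in × 100 closes to the solver residual.
    The pointwise error is the steady-state residual of every non-Dirichlet
    equation normalized by the local throughput, ∞-norm, in percent.
    """
    cv, ct = solution.cv, solution.ct
    inlet = float(np.sum(system.inlet_flux * cv[system.inlet_nodes]))
    outlet = float(np.sum(system.outlet_flux * cv[system.outlet_nodes]))
    node_c, cell_c, g_c = system.couplings
    _, index = _tissue_index(system)
    transfer = float(np.sum(g_c * (cv[node_c] - ct[index[cell_c]])))
    if inlet <= 0:
        raise AuditError("zero oxygen inlet feed: audit undefined")
    loss = abs(inlet - outlet - transfer) / inlet * 100.0

    # pointwise steady-state residuals in every non-Dirichlet balance,
    # normalized by the total inlet feed (the same scale as the loss term;
    # a per-row throughput normalization degenerates to 0/0 noise in
    # stagnant regions at machine precision)
    x = np.concatenate([cv, ct])
    r = system.A @ x - system.b
    rel = np.abs(r) / inlet
    rel[system.dirichlet_rows] = 0.0
    return MassAudit(
        flow=flow_audit,
        oxygen_inlet=inlet,
        oxygen_outlet=outlet,
        oxygen_transfer=transfer,
        oxygen_loss_percent=loss,
        max_balance_error_percent=float(np.max(rel)) * 100.0,
    )


def _tissue_index(system: TransportSystem):
    tissue = system.tissue_cells
    index = np.full(system.grid.n_cells, -1, dtype=np.int64)
    index[tissue] = np.arange(tissue.size)
    return tissue, index


# ---------------------------------------------------------------------------
# Raytracing
# ---------------------------------------------------------------------------

def default_rays(grid: CartesianGrid, n: int = 25):
    """n vertical rays on a √n × √n in-plane lattice through the domain."""
    side = int(round(np.sqrt(n)))
    lo, hi = grid.bounds
    xs = lo[0] + (np.arange(side) + 0.5) / side * (hi[0] - lo[0])
    ys = lo[1] + (np.arange(side) + 0.5) / side * (hi[1] - lo[1])
    rays = []
    for x in xs:
        for y in ys:
            rays.append(((x, y, lo[2]), (0.0, 0.0, 1.0)))
    return rays[:n]


def raytrace_profiles(solution: OxygenSolution, rays=None, n_samples: int = 100):
    """Sample pO2 along rays by trilinear interpolation of cell centers.

    Returns ``(profiles, arclengths)``: profiles is (n_rays, n_samples);
    rays that miss the domain yield an all-NaN profile (flagged empty).
    """
    grid = solution.system.grid
    field = solution.reconstructed_field()
    if rays is None:
        rays = default_rays(grid, 25)
    lo, hi = grid.bounds
    profiles = np.full((len(rays), n_samples), np.nan)
    arcs = np.zeros((len(rays), n_samples))
    for i, (origin, direction) in enumerate(rays):
        o = np.asarray(origin, float)
        u = np.asarray(direction, float)
        u = u / np.linalg.norm(u)
        # slab-clip the ray to the domain box
        tmin, tmax = -np.inf, np.inf
        miss = False
        for a in range(3):
            if abs(u[a]) < 1e-15:
                if not (lo[a] <= o[a] <= hi[a]):
                    miss = True
                    break
                continue
            ta = (lo[a] - o[a]) / u[a]
            tb = (hi[a] - o[a]) / u[a]
            tmin = max(tmin, min(ta, tb))
            tmax = min(tmax, max(ta, tb))
        tmin = max(tmin, 0.0)
        if miss or not np.isfinite(tmax) or tmax <= tmin:
            continue  # ray misses the domain
        t = np.linspace(tmin, tmax, n_samples)
        pts = o + t[:, None] * u
        profiles[i] = interpolate_field(grid, field, pts)
        arcs[i] = t
    return profiles, arcs


def profile_deviation(profiles, reference):
    """Per-ray max |Δ| between two profile sets plus summary statistics."""
    diff = np.abs(np.asarray(profiles) - np.asarray(reference))
    per_ray = np.nanmax(diff, axis=1)
    return {
        "per_ray_max": per_ray,
        "max": float(np.nanmax(per_ray)),
        "mean": float(np.nanmean(per_ray)),
    }


# ---------------------------------------------------------------------------
# Hypoxia
# ---------------------------------------------------------------------------

def hypoxic_fraction(
    solution: OxygenSolution,
    thresholds=HYPOXIA_THRESHOLDS,
    roi=None,
):
    """Fraction of tissue (non-lumen) cells below each pO2 threshold.

    ``roi`` is an optional ((x0,y0,z0), (x1,y1,z1)) box in µm restricting
    the tally.  Also reports the 6-connected hypoxic components and their
    voxel volumes for each threshold.
    """
    grid = solution.system.grid
    labels = solution.system.labels
    field = solution.reconstructed_field()
    tissue = labels.label != INTERIOR
    mask = tissue & _roi_mask(grid, roi)
    total = int(np.count_nonzero(mask))
    if total == 0:
        raise ParameterError("empty ROI: no tissue cells to tally")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    out = {}
    for thr in thresholds:
        hyp = mask & (field < thr)
        lab, n_comp = ndimage.label(hyp, structure=structure)
        volumes = (
            np.bincount(lab.ravel())[1:] * grid.cell_volume if n_comp else np.empty(0)
        )
        out[float(thr)] = {
            "fraction": float(np.count_nonzero(hyp)) / total,
            "n_components": int(n_comp),
            "component_volumes_um3": volumes,
        }
    return out


def _roi_mask(grid: CartesianGrid, roi):
    if roi is None:
        return np.ones(grid.shape, bool)
    (x0, y0, z0), (x1, y1, z1) = roi
    cx = grid.axis_centers(0)
    cy = grid.axis_centers(1)
    cz = grid.axis_centers(2)
    return (
        ((cx >= x0) & (cx <= x1))[:, None, None]
        & ((cy >= y0) & (cy <= y1))[None, :, None]
        & ((cz >= z0) & (cz <= z1))[None, None, :]
    )


def extract_roi(grid: CartesianGrid, field: np.ndarray, box):
    """Crop a cell-centered field to the cells strictly inside a µm box.

    Returns ``(sub_grid, sub_field)``.  A box exceeding the domain is
    clipped with a warning.
    """
    lo, hi = grid.bounds
    (x0, y0, z0), (x1, y1, z1) = box
    blo = np.asarray([x0, y0, z0], float)
    bhi = np.asarray([x1, y1, z1], float)
    if np.any(blo < lo - 1e-9) or np.any(bhi > hi + 1e-9):
        warnings.warn("ROI box exceeds domain: clipped", stacklevel=2)
        blo = np.maximum(blo, lo)
        bhi = np.minimum(bhi, hi)
    i0 = np.ceil((blo - np.asarray(grid.origin)) / grid.spacing - 0.5).astype(int)
    i1 = np.floor((bhi - np.asarray(grid.origin)) / grid.spacing - 0.5).astype(int)
    i0 = np.maximum(i0, 0)
    i1 = np.minimum(i1, np.asarray(grid.shape) - 1)
    sub = field[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1]
    sub_grid = CartesianGrid(
        tuple(np.asarray(grid.origin) + i0 * grid.spacing),
        grid.spacing,
        sub.shape,
    )
    return sub_grid, sub


def extract_roi_network(net: VascularNetwork, box) -> VascularNetwork:
    """Sub-network of segments with both endpoints inside the box."""
    (x0, y0, z0), (x1, y1, z1) = box
    lo = np.asarray([x0, y0, z0])
    hi = np.asarray([x1, y1, z1])
    inside = np.all((net.node_xyz >= lo) & (net.node_xyz <= hi), axis=1)
    keep = inside[net.seg_head] & inside[net.seg_tail]
    used = np.unique(np.r_[net.seg_head[keep], net.seg_tail[keep]])
    remap = np.full(net.n_nodes, -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    return VascularNetwork(
        node_xyz=net.node_xyz[used],
        seg_head=remap[net.seg_head[keep]],
        seg_tail=remap[net.seg_tail[keep]],
        diameter=net.diameter[keep],
        vessel_class=net.vessel_class[keep],
        occluded=net.occluded[keep],
        node_labels=net.node_labels[used],
        seg_labels=net.seg_labels[keep],
        metadata=dict(net.metadata),
    )


# ---------------------------------------------------------------------------
# Depth planes and coarse-average maps
# ---------------------------------------------------------------------------

def depth_plane_map(solution: OxygenSolution, depths=DEPTH_PLANES):
    """Extract the cell layer nearest each cortical depth as a 2D map.

    Returns {depth: (k_index, 2D array)}; depths outside the domain are
    skipped with a warning.
    """
    grid = solution.system.grid
    field = solution.reconstructed_field()
    cz = grid.axis_centers(2)
    lo, hi = grid.bounds
    out = {}
    for depth in depths:
        if depth < lo[2] or depth > hi[2]:
            warnings.warn(f"depth {depth} µm outside domain: skipped", stacklevel=2)
            continue
        k = int(np.argmin(np.abs(cz - depth)))
        out[float(depth)] = (k, field[:, :, k].copy())
    return out


def coarse_average_map(dense: np.ndarray, coarse_shape=(20, 20)):
    """Block-average a dense in-plane map onto a coarse raster.

    If the dense shape is not divisible by the coarse shape, the nearest
    divisible partition is used (trailing rows/cols dropped, with a
    warning).
    """
    dense = np.asarray(dense, float)
    cs = tuple(coarse_shape)
    crop = [d - d % c for d, c in zip(dense.shape, cs)]
    if tuple(crop) != dense.shape:
        warnings.warn(
            f"dense shape {dense.shape} not divisible by {cs}: cropped to {crop}",
            stacklevel=2,
        )
    d = dense[: crop[0], : crop[1]]
    bx, by = crop[0] // cs[0], crop[1] // cs[1]
    return d.reshape(cs[0], bx, cs[1], by).mean(axis=(1, 3))


def mean_relative_error_percent(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Mean |predicted − reference| / mean(reference) × 100 (map comparison)."""
    predicted = np.asarray(predicted, float)
    reference = np.asarray(reference, float)
    scale = float(np.mean(np.abs(reference)))
    if scale == 0:
        return 0.0 if np.allclose(predicted, reference) else np.inf
    return float(np.mean(np.abs(predicted - reference)) / scale * 100.0)


# ---------------------------------------------------------------------------
# Aging scenarios
# ---------------------------------------------------------------------------

def aging_scenario(
    net: VascularNetwork,
    bc: BoundaryConditionSet,
    occlusion_fraction: float = 0.30,
    hematocrit_factor: float = 0.70,
    seed: int = 0,
    mode: str = "combined",
):
    """Impose age-related perturbations in silico.

    ``mode``: 'young' (identity), 'occlusions' (occlude a seeded uniform
    sample of ⌊fraction · n_capillaries⌋ capillaries by setting their
    diameter to numerical zero), 'hematocrit' (scale all inlet h̄ by the
    factor), or 'combined'.  Returns perturbed copies ``(net, bc)``.
    """
    if not (0.0 <= occlusion_fraction <= 1.0):
        raise ParameterError("occlusion_fraction must lie in [0, 1]")
    if not (0.0 < hematocrit_factor <= 1.0):
        raise ParameterError("hematocrit_factor must lie in (0, 1]")
    if mode not in ("young", "occlusions", "hematocrit", "combined"):
        raise ParameterError(f"unknown scenario mode {mode!r}")
    net2 = net.copy()
    bc2 = bc.copy()
    if mode in ("occlusions", "combined") and occlusion_fraction > 0:
        caps = np.flatnonzero(net2.vessel_class == "capillary")
        if caps.size == 0:
            raise ParameterError("network has no classified capillaries to occlude")
        n_occ = int(np.floor(occlusion_fraction * caps.size))
        rng = np.random.default_rng(seed)
        chosen = rng.choice(caps, size=n_occ, replace=False)
        net2.occluded[chosen] = True
        net2.diameter[chosen] = 0.0  # numerical-zero diameter
    if mode in ("hematocrit", "combined"):
        bc2.inlet_hematocrit = {
            k: v * hematocrit_factor for k, v in bc2.inlet_hematocrit.items()
        }
    return net2, bc2
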