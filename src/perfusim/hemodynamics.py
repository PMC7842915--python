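"""Biphasic blood flow: pressure/flow and hematocrit with plasma skimming.

Flow obeys Hagen–Poiseuille per segment with a hematocrit- and
diameter-dependent apparent viscosity; nodal Kirchhoff balances close the
linear pressure problem.  Hematocrit is transported by upwinding: nodes mix
inflowing RBC flux, diverging bifurcations split it by the skimming model.
The two fields are coupled by fixed-point iteration.

Units: µm, s, mmHg.  Flow is µm³/s (1 nL/s = 1e6 µm³/s); resistance
mmHg·s/µm³; viscosity mmHg·s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import AuditError, NonConvergenceError, ParameterError, SolverError
from .network import BoundaryConditionSet, VascularNetwork, incidence_matrix

#: mmHg·s per Pa·s (1 mmHg = 133.322 Pa)
MMHG_S_PER_PA_S = 1.0 / 133.322
#: plasma viscosity, 1.2 cP expressed in mmHg·s
PLASMA_VISCOSITY = 1.2e-3 * MMHG_S_PER_PA_S
#: resistance assigned to occluded ("numerical zero" diameter) segments
OCCLUDED_RESISTANCE = 1e30
#: |f| below this multiple of mean |f| counts as stagnant
STAGNANT_REL = 1e-15

NL_PER_S = 1e6  # µm³/s per nL/s


def relative_viscosity_in_vitro(d: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Empirical in vitro tube relative viscosity µ_rel(d, h).

    Classic phase-separation fit for blood flowing in glass tubes: the
    apparent viscosity has a pronounced minimum near capillary calibers
    (the Fåhræus–Lindqvist effect) and rises steeply with hematocrit.
    ``d`` in µm, ``h`` dimensionless tube hematocrit.
    """
    d = np.asarray(d, float)
    h = np.asarray(h, float)
    mu45 = 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)
    frac = 1.0 / (1.0 + 1e-11 * d**12)
    c = (0.8 + np.exp(-0.075 * d)) * (-1.0 + frac) + frac
    num = (1.0 - h) ** c - 1.0
    den = (1.0 - 0.45) ** c - 1.0
    return 1.0 + (mu45 - 1.0) * num / den


def segment_resistance(
    d, L, h=0.0, viscosity_model: str = "constant", mu_plasma: float = PLASMA_VISCOSITY
):
    """Hydraulic resistance R = 128 µ(d, h) L / (π d⁴) in mmHg·s/µm³."""
    d = np.asarray(d, float)
    L = np.asarray(L, float)
    h = np.broadcast_to(np.asarray(h, float), d.shape) if d.shape else np.asarray(h, float)
    if np.any(d <= 0):
        raise ParameterError(
            "nonpositive diameter: occluded segments must use the occlusion path"
        )
    if np.any(L <= 0):
        raise ParameterError("nonpositive segment length")
    if viscosity_model == "constant":
        mu = mu_plasma
    elif viscosity_model == "in_vitro":
        mu = mu_plasma * relative_viscosity_in_vitro(d, h)
    else:
        raise ParameterError(f"unknown viscosity model {viscosity_model!r}")
    return 128.0 * mu * L / (np.pi * d**4)


def _resistances(net: VascularNetwork, h, viscosity_model, mu_plasma):
    R = np.full(net.n_segments, OCCLUDED_RESISTANCE)
    ok = ~net.occluded & (net.diameter > 0)
    if np.any(ok):
        hh = np.broadcast_to(np.asarray(h, float), (net.n_segments,))
        R[ok] = segment_resistance(
            net.diameter[ok], net.lengths[ok], hh[ok], viscosity_model, mu_plasma
        )
    return R


def solve_flow(
    net: VascularNetwork,
    bc: BoundaryConditionSet,
    h=0.35,
    viscosity_model: str = "constant",
    mu_plasma: float = PLASMA_VISCOSITY,
):
    """Solve the linear pressure/flow problem for a fixed hematocrit field.

    Returns ``(f, p)``: signed segment flows (positive head -> tail) and
    node pressures.  Dirichlet pressures and Neumann injections are taken
    from ``bc``; the nodal system is the weighted graph Laplacian
    C1ᵀ R⁻¹ C1 with Dirichlet rows replaced.
    """
    if not bc.pressure:
        raise SolverError("flow problem needs at least one pressure Dirichlet node")
    R = _resistances(net, h, viscosity_model, mu_plasma)
    g = 1.0 / R
    n = net.n_nodes
    hd, tl = net.seg_head, net.seg_tail
    L = sp.coo_matrix(
        (
            np.r_[g, g, -g, -g],
            (np.r_[hd, tl, hd, tl], np.r_[hd, tl, tl, hd]),
        ),
        shape=(n, n),
    ).tocsr()
    rhs = np.zeros(n)
    for node, q in bc.flow.items():
        rhs[node] += q

    dir_nodes = np.fromiter(bc.pressure.keys(), dtype=np.int64)
    L = L.tolil()
    for node in dir_nodes:
        L.rows[node] = [int(node)]
        L.data[node] = [1.0]
        rhs[node] = bc.pressure[node]
    p = spla.spsolve(L.tocsr(), rhs)
    if not np.all(np.isfinite(p)):
        raise SolverError("flow system is singular (disconnected from Dirichlet nodes?)")
    f = g * (p[hd] - p[tl])
    return f, p


def _upwind_order(net: VascularNetwork, f: np.ndarray, active: np.ndarray):
    """Kahn topological order of nodes over the flow-directed active segments.

    Returns (order, ok): ok is False when a directed cycle prevents a
    topological order (caller then falls back to the linear system).
    """
    n = net.n_nodes
    up = np.where(f >= 0, net.seg_head, net.seg_tail)
    dn = np.where(f >= 0, net.seg_tail, net.seg_head)
    indeg = np.zeros(n, dtype=np.int64)
    np.add.at(indeg, dn[active], 1)
    out_lists = [[] for _ in range(n)]
    for s in np.flatnonzero(active):
        out_lists[up[s]].append(s)
    from collections import deque

    queue = deque(np.flatnonzero(indeg == 0).tolist())
    order = []
    indeg = indeg.copy()
    while queue:
        v = queue.popleft()
        order.append(v)
        for s in out_lists[v]:
            w = dn[s]
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return order, len(order) == n


def solve_hematocrit(
    net: VascularNetwork,
    f: np.ndarray,
    bc: BoundaryConditionSet,
    skimming_model: str = "proportional",
    skim_exponent: float = 1.0,
):
    """Transport hematocrit through a converged flow field.

    Nodes are visited in upwind (flow-topological) order; each node's value
    is the flux-weighted mix of its inflows; diverging bifurcations split
    the RBC flux among daughters by the skimming model ("proportional":
    daughter RBC flux ∝ daughter bulk flow, hence h preserved;
    "threshold_skim": daughter share ∝ flowᵞ, renormalized and capped at
    h ≤ 1 with conservative redistribution).  If a directed cycle blocks the
    ordering, the nodal linear system M̄c h = D0 h̄ is solved instead.
    Returns per-segment hematocrit; stagnant segments take the mean of
    their endpoints' nodal values.
    """
    if skimming_model not in ("proportional", "threshold_skim"):
        raise ParameterError(f"unknown skimming model {skimming_model!r}")
    n = net.n_nodes
    f = np.asarray(f, float)
    mean_f = np.mean(np.abs(f)) if f.size else 0.0
    active = (np.abs(f) > STAGNANT_REL * mean_f) & ~net.occluded

    up = np.where(f >= 0, net.seg_head, net.seg_tail)
    dn = np.where(f >= 0, net.seg_tail, net.seg_head)
    q = np.abs(f)

    # inflow boundary nodes: net flow enters the network there
    net_out = np.zeros(n)
    np.add.at(net_out, up, q)
    np.add.at(net_out, dn, -q)
    # safely above direct-solver Kirchhoff noise, far below physical inflows
    tol = 1e-9 * (np.max(q) if q.size else 0.0) + 1e-300
    inlet_nodes = [v for v in range(n) if net_out[v] > tol]
    missing = [v for v in inlet_nodes if v not in bc.inlet_hematocrit]
    if missing:
        raise ParameterError(
            f"inflow boundary nodes without inlet hematocrit: {missing}"
        )

    order, ok = _upwind_order(net, f, active)
    if not ok:
        return _hematocrit_linear(net, f, bc, active, up, dn, q, inlet_nodes)

    in_lists = [[] for _ in range(n)]
    out_lists = [[] for _ in range(n)]
    for s in np.flatnonzero(active):
        in_lists[dn[s]].append(s)
        out_lists[up[s]].append(s)

    h_node = np.full(n, np.nan)
    h_seg = np.full(net.n_segments, np.nan)
    for v in inlet_nodes:
        h_node[v] = bc.inlet_hematocrit[v]
    default = (
        float(np.mean(list(bc.inlet_hematocrit.values())))
        if bc.inlet_hematocrit
        else 0.0
    )
    for v in order:
        if np.isnan(h_node[v]):
            inflows = in_lists[v]
            if inflows:
                qs = q[inflows]
                h_node[v] = float(np.dot(qs, h_seg[inflows]) / qs.sum())
            else:
                h_node[v] = default  # stagnant/isolated node
        outs = out_lists[v]
        if not outs:
            continue
        if skimming_model == "proportional" or len(outs) == 1:
            h_seg[outs] = h_node[v]
        else:
            qs = q[outs]
            share = qs**skim_exponent
            share = share / share.sum()
            rbc = h_node[v] * qs.sum()
            hh = rbc * share / qs
            # cap at 1 and push the excess back proportionally to bulk flow
            for _ in range(len(outs)):
                over = hh > 1.0
                if not np.any(over):
                    break
                excess = float(np.dot(qs[over], hh[over] - 1.0))
                hh[over] = 1.0
                room = ~over & (hh < 1.0)
                if not np.any(room):
                    break
                hh[room] += excess / qs[room].sum()
            h_seg[outs] = hh
    # stagnant segments: mean of endpoint nodal values (no transport)
    stag = ~active
    if np.any(stag):
        hn = np.where(np.isnan(h_node), default, h_node)
        h_seg[stag] = 0.5 * (hn[net.seg_head[stag]] + hn[net.seg_tail[stag]])
    return np.clip(h_seg, 0.0, 1.0)


def _hematocrit_linear(net, f, bc, active, up, dn, q, inlet_nodes):
    """Nodal linear system fallback for cyclic flow patterns."""
    n = net.n_nodes
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    q_in = np.zeros(n)
    np.add.at(q_in, dn[active], q[active])
    adj = net.adjacency()
    inlet = set(inlet_nodes)
    for v in range(n):
        if v in inlet:
            rows.append(v); cols.append(v); vals.append(1.0)
            rhs[v] = bc.inlet_hematocrit[v]
        elif q_in[v] > 0:
            rows.append(v); cols.append(v); vals.append(q_in[v])
            for s in np.flatnonzero(active & (dn == v)):
                rows.append(v); cols.append(up[s]); vals.append(-q[s])
        else:
            nbrs = adj.indices[adj.indptr[v]:adj.indptr[v + 1]]
            rows.append(v); cols.append(v); vals.append(1.0)
            for w in nbrs:
                rows.append(v); cols.append(int(w)); vals.append(-1.0 / len(nbrs))
            if len(nbrs) == 0:
                rhs[v] = 0.0
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    h_node = spla.spsolve(M, rhs)
    h_seg = np.where(
        active,
        h_node[up],
        0.5 * (h_node[net.seg_head] + h_node[net.seg_tail]),
    )
    return np.clip(h_seg, 0.0, 1.0)


@dataclass
class FlowSolution:
    """Converged biphasic flow state."""

    f: np.ndarray  # segment flow, µm³/s, signed head -> tail
    p: np.ndarray  # node pressure, mmHg
    h: np.ndarray  # segment hematocrit
    iterations: int
    residual: float
    history: list = field(default_factory=list)


def fixed_point_hemodynamics(
    net: VascularNetwork,
    bc: BoundaryConditionSet,
    viscosity_model: str = "in_vitro",
    skimming_model: str = "proportional",
    tol: float = 1e-6,
    max_iter: int = 100,
    mu_plasma: float = PLASMA_VISCOSITY,
) -> FlowSolution:
    """Alternate flow and hematocrit solves until both fields settle.

    Convergence: max relative change of f (scaled by max |f|) and of h both
    below ``tol``.  Raises after ``max_iter`` without convergence, or if the
    change grows over 10 consecutive iterations.
    """
    bc.validate(net)
    h = np.full(
        net.n_segments,
        float(np.mean(list(bc.inlet_hematocrit.values())))
        if bc.inlet_hematocrit
        else 0.0,
    )
    f_prev = None
    history = []
    grow = 0
    for it in range(1, max_iter + 1):
        f, p = solve_flow(net, bc, h, viscosity_model, mu_plasma)
        if bc.inlet_hematocrit:
            h_new = solve_hematocrit(net, f, bc, skimming_model)
        else:
            h_new = h.copy()
        if f_prev is None:
            change = np.inf
        else:
            scale = max(np.max(np.abs(f)), 1e-300)
            change = max(
                float(np.max(np.abs(f - f_prev)) / scale),
                float(np.max(np.abs(h_new - h))),
            )
        history.append(change)
        if len(history) >= 2 and np.isfinite(history[-2]):
            grow = grow + 1 if change > history[-2] else 0
            if grow >= 10:
                raise NonConvergenceError(
                    "fixed-point iteration diverging", history=history
                )
        f_prev, h = f, h_new
        if change < tol:
            return FlowSolution(f, p, h, it, change, history)
    raise NonConvergenceError(
        f"fixed point did not converge in {max_iter} iterations", history=history
    )


# ---------------------------------------------------------------------------
# Audit
# ---------------------------------------------------------------------------

@dataclass
class FlowAudit:
    """Blood-flow conservation report (Table-style)."""

    inflow: float          # µm³/s
    outflow: float         # µm³/s
    loss_percent: float    # |in − out| / in × 100
    max_imbalance_percent: float  # worst nodal residual / total inflow × 100

    @property
    def inflow_nl_per_s(self) -> float:
        return self.inflow / NL_PER_S

    @property
    def outflow_nl_per_s(self) -> float:
        return self.outflow / NL_PER_S


def flow_mass_audit(net: VascularNetwork, bc: BoundaryConditionSet,
                    f: np.ndarray) -> FlowAudit:
    """Total boundary inflow/outflow and normalized loss of a flow field."""
    C1 = incidence_matrix(net)
    r = C1.T @ f  # net flow leaving each node through its segments
    boundary = set(bc.pressure) | set(bc.flow)
    # Neumann injections are sources; fold them into the nodal residual
    for node, q in bc.flow.items():
        r[node] -= q
    b = np.fromiter(boundary, dtype=np.int64) if boundary else np.empty(0, np.int64)
    inflow = float(np.sum(np.maximum(r[b], 0.0))) + sum(
        max(q, 0.0) for q in bc.flow.values()
    )
    outflow = float(np.sum(np.maximum(-r[b], 0.0))) + sum(
        max(-q, 0.0) for q in bc.flow.values()
    )
    if inflow <= 0:
        raise AuditError("zero total inflow: audit undefined")
    interior = np.ones(net.n_nodes, bool)
    interior[b] = False
    max_imb = float(np.max(np.abs(r[interior]))) if np.any(interior) else 0.0
    return FlowAudit(
        inflow=inflow,
        outflow=outflow,
        loss_percent=abs(inflow - outflow) / inflow * 100.0,
        max_imbalance_percent=max_imb / inflow * 100.0,
    )
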