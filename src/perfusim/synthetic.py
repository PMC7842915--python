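"""Synthetic cortical microvascular networks and analytic test fixtures.

The generator emulates the essential architecture of cortical angioarchitecture
at desk scale: penetrating arteriolar and venular trees descending from the
pial surface (z = 0), joined by a randomized capillary lattice at a target
density of ~11,600 segments/mm³.  It is a deliberately simple stand-in for
image-based network synthesis: dyadic trunks with Murray-style diameter taper
(child = parent × 2^(−1/3)) feed a jittered 3D grid of capillaries in which
every segment lies on an inlet→outlet path.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .errors import ParameterError, ValidationError
from .network import BoundaryConditionSet, VascularNetwork

#: cortical capillary density target, segments per mm³ of tissue
DEFAULT_DENSITY = 11600.0

DEFAULT_DIAMETERS = {
    "penetrating_root": (20.0, 40.0),
    "capillary": (3.0, 5.5),
}


def generate_cortex_network(
    extent=(300.0, 300.0, 300.0),
    target_density: float = DEFAULT_DENSITY,
    n_penetrating_pairs: int = 1,
    diameter_ranges: dict | None = None,
    pressure_drop: float = 115.0,
    inlet_hematocrit: float = 0.35,
    inlet_oxygen: float = 68.5,
    seed: int = 0,
):
    """Generate a synthetic cortical network with boundary conditions.

    Returns ``(VascularNetwork, BoundaryConditionSet)``: pressure Dirichlet
    BCs sit on the pial arteriole roots (``pressure_drop`` mmHg) and venule
    roots (0 mmHg); inlet hematocrit and oxygen tension are attached to the
    arterial roots.  The achieved segment density is within 20% of
    ``target_density`` or a :class:`ParameterError` reports the achievable
    range.  Fully reproducible for a fixed seed.
    """
    extent = np.asarray(extent, float)
    if np.any(extent <= 0):
        raise ParameterError("extent must be positive")
    if n_penetrating_pairs < 1:
        raise ParameterError("need at least one arteriole/venule pair")
    ranges = dict(DEFAULT_DIAMETERS)
    if diameter_ranges:
        ranges.update(diameter_ranges)
    rng = np.random.default_rng(seed)

    volume_mm3 = float(np.prod(extent)) * 1e-9
    target_total = target_density * volume_mm3

    # capillary lattice: grid edges ~ 3 n³ at spacing s -> s = (3/ρ)^(1/3),
    # then a small per-axis count search compensates finite-size effects
    rho = target_density * 1e-9  # per µm³
    s = (3.0 / rho) ** (1.0 / 3.0)

    def lattice_edges(c):
        cx, cy, cz = c
        return (cx - 1) * cy * cz + cx * (cy - 1) * cz + cx * cy * (cz - 1)

    def tree_segments(c):
        sz = extent[2] / c[2]
        n_trunk = len(np.arange(0.5 * sz, extent[2] * 0.85, 1.5 * sz))
        return n_penetrating_pairs * 2 * 2 * n_trunk

    base = np.maximum(np.floor(extent / s).astype(int), 2)
    best, best_err = None, np.inf
    for di in range(3):
        for dj in range(3):
            for dk in range(3):
                c = np.maximum(base + np.array([di, dj, dk]), 2)
                total = lattice_edges(c) + tree_segments(c)
                err = abs(total / volume_mm3 - target_density)
                if err < best_err:
                    best, best_err = c, err
    counts = best
    achieved = (lattice_edges(counts) + tree_segments(counts)) / volume_mm3
    if not (0.8 * target_density <= achieved <= 1.2 * target_density):
        raise ParameterError(
            f"target density {target_density:.0f}/mm³ not achievable on extent "
            f"{tuple(extent)}; nearest achievable is {achieved:.0f}/mm³ "
            "(use a larger extent or a different density)"
        )

    spacing = extent / counts
    # jittered lattice node positions
    idx = np.stack(
        np.meshgrid(*(np.arange(c) for c in counts), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    base = (idx + 0.5) * spacing
    jitter = rng.uniform(-0.25, 0.25, size=base.shape) * spacing
    xyz = [base + jitter]
    lat_lin = (
        idx[:, 0] * counts[1] * counts[2] + idx[:, 1] * counts[2] + idx[:, 2]
    )
    lat_index = {int(l): i for i, l in enumerate(lat_lin)}

    def lat_id(i, j, k):
        return lat_index[int(i * counts[1] * counts[2] + j * counts[2] + k)]

    heads, tails, diams, classes = [], [], [], []
    cap_lo, cap_hi = ranges["capillary"]
    for axis in range(3):
        for i in range(counts[0] - (axis == 0)):
            for j in range(counts[1] - (axis == 1)):
                for k in range(counts[2] - (axis == 2)):
                    a = lat_id(i, j, k)
                    b = lat_id(i + (axis == 0), j + (axis == 1), k + (axis == 2))
                    heads.append(a)
                    tails.append(b)
                    diams.append(rng.uniform(cap_lo, cap_hi))
                    classes.append("capillary")

    nodes = list(map(tuple, xyz[0]))
    all_xyz = [np.asarray(p, float) for p in nodes]

    def add_node(p):
        all_xyz.append(np.asarray(p, float))
        return len(all_xyz) - 1

    # penetrating trees: trunk descending from z=0 with connectors into the
    # lattice; arterial and venous roots at mirrored in-plane positions
    root_lo, root_hi = ranges["penetrating_root"]
    taper = 2.0 ** (-1.0 / 3.0)
    bc = BoundaryConditionSet()
    trunk_z = np.arange(0.5 * spacing[2], extent[2] * 0.85, 1.5 * spacing[2])
    lattice_xyz = np.asarray(all_xyz[: len(nodes)])

    def build_tree(x, y, venous: bool):
        root = add_node((x, y, 0.0))
        d = rng.uniform(root_lo, root_hi)
        prev = root
        cls = "venule" if venous else "penetrating_arteriole"
        used = set()
        for depth in trunk_z:
            node = add_node((x, y, depth))
            heads.append(prev if not venous else node)
            tails.append(node if not venous else prev)
            diams.append(max(d, 6.0))
            classes.append(cls)
            # connector to the nearest unused lattice node
            dist = np.linalg.norm(lattice_xyz - np.asarray([x, y, depth]), axis=1)
            order = np.argsort(dist)
            target = next(int(t) for t in order if t not in used)
            used.add(target)
            heads.append(node if not venous else target)
            tails.append(target if not venous else node)
            diams.append(max(d * taper, 6.0))
            classes.append(cls)
            d = max(d * taper, 6.0)
            prev = node
        return root

    for pair in range(n_penetrating_pairs):
        if n_penetrating_pairs == 1:
            fa, fv = (0.3, 0.3), (0.7, 0.7)
        else:
            fa = rng.uniform(0.15, 0.45, size=2)
            fv = rng.uniform(0.55, 0.85, size=2)
        a_root = build_tree(fa[0] * extent[0], fa[1] * extent[1], venous=False)
        v_root = build_tree(fv[0] * extent[0], fv[1] * extent[1], venous=True)
        bc.pressure[a_root] = pressure_drop
        bc.pressure[v_root] = 0.0
        bc.inlet_hematocrit[a_root] = inlet_hematocrit
        bc.inlet_oxygen[a_root] = inlet_oxygen

    net = VascularNetwork(
        node_xyz=np.asarray(all_xyz),
        seg_head=np.asarray(heads, dtype=np.int64),
        seg_tail=np.asarray(tails, dtype=np.int64),
        diameter=np.asarray(diams, float),
        vessel_class=np.asarray(classes, dtype=object),
        metadata={"seed": seed, "extent_um": tuple(extent),
                  "target_density_per_mm3": target_density},
    )
    net.validate()
    bc.validate(net)
    assert_perfused(net, bc)
    return net, bc


def assert_perfused(net: VascularNetwork, bc: BoundaryConditionSet) -> None:
    """Every node must be reachable from an inlet and from an outlet through
    the non-occluded graph (no perfusion dead ends)."""
    adj = net.adjacency()
    inlets = [n for n in bc.pressure if n in bc.inlet_hematocrit or n in bc.inlet_oxygen]
    outlets = [n for n in bc.pressure if n not in inlets]
    if not inlets or not outlets:
        raise ValidationError("need both inlet and outlet boundary nodes")

    def reach(roots):
        mask = np.zeros(net.n_nodes, bool)
        for r in roots:
            if not mask[r]:
                order = sp.csgraph.breadth_first_order(
                    adj, r, directed=False, return_predecessors=False
                )
                mask[order] = True
        return mask

    from_in = reach(inlets)
    from_out = reach(outlets)
    # only check endpoints of non-occluded segments (isolated nodes are inert)
    keep = ~net.occluded
    ok = from_in & from_out
    if not np.all(ok[net.seg_head[keep]] & ok[net.seg_tail[keep]]):
        bad = np.flatnonzero(~(ok[net.seg_head] & ok[net.seg_tail]) & keep)
        raise ValidationError(
            f"{bad.size} segments are not on any inlet→outlet path"
        )


# ---------------------------------------------------------------------------
# Analytic fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, **params):
    """Small analytic configurations with closed-form expectations.

    Kinds: ``single_vessel`` (one straight pressure-driven segment),
    ``y_bifurcation`` (mirror-symmetric diverging daughters),
    ``krogh_cylinder`` (one axial vessel centered in a tissue box),
    ``two_vessel_counterflow`` (two parallel vessels, opposite flow).
    Returns ``(VascularNetwork, BoundaryConditionSet)``.
    """
    if kind == "single_vessel":
        return _single_vessel(**params)
    if kind == "y_bifurcation":
        return _y_bifurcation(**params)
    if kind == "krogh_cylinder":
        return _krogh_cylinder(**params)
    if kind == "two_vessel_counterflow":
        return _two_vessel_counterflow(**params)
    raise ParameterError(f"unknown fixture kind {kind!r}")


def _base_bc(inlets, outlets, dp, hematocrit, oxygen):
    bc = BoundaryConditionSet()
    for n in inlets:
        bc.pressure[n] = dp
        bc.inlet_hematocrit[n] = hematocrit
        bc.inlet_oxygen[n] = oxygen
    for n in outlets:
        bc.pressure[n] = 0.0
    return bc


def _single_vessel(L=100.0, d=10.0, dp=1.0, hematocrit=0.35, oxygen=68.5,
                   origin=(0.0, 0.0, 0.0), axis=(1.0, 0.0, 0.0)):
    o = np.asarray(origin, float)
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    net = VascularNetwork(
        node_xyz=np.asarray([o, o + L * u]),
        seg_head=[0],
        seg_tail=[1],
        diameter=[d],
    )
    return net, _base_bc([0], [1], dp, hematocrit, oxygen)


def _y_bifurcation(L_parent=100.0, L_daughter=80.0, d_parent=12.0,
                   d_daughter=8.0, angle_deg=35.0, dp=1.0,
                   hematocrit=0.35, oxygen=68.5):
    th = np.deg2rad(angle_deg)
    p = np.asarray(
        [
            [0.0, 0.0, 0.0],
            [L_parent, 0.0, 0.0],
            [L_parent + L_daughter * np.cos(th), L_daughter * np.sin(th), 0.0],
            [L_parent + L_daughter * np.cos(th), -L_daughter * np.sin(th), 0.0],
        ]
    )
    net = VascularNetwork(
        node_xyz=p,
        seg_head=[0, 1, 1],
        seg_tail=[1, 2, 3],
        diameter=[d_parent, d_daughter, d_daughter],
    )
    return net, _base_bc([0], [2, 3], dp, hematocrit, oxygen)


def _krogh_cylinder(L=100.0, d=8.0, box_width=60.0, dp=1.0,
                    hematocrit=0.35, oxygen=68.5):
    c = 0.5 * box_width
    net = VascularNetwork(
        node_xyz=np.asarray([[c, c, 0.0], [c, c, L]]),
        seg_head=[0],
        seg_tail=[1],
        diameter=[d],
        metadata={"box_extent_um": (box_width, box_width, L)},
    )
    return net, _base_bc([0], [1], dp, hematocrit, oxygen)


def _two_vessel_counterflow(L=100.0, d=8.0, separation=40.0, dp=1.0,
                            hematocrit=0.35, oxygen=68.5):
    y0, y1 = 0.0, separation
    net = VascularNetwork(
        node_xyz=np.asarray(
            [
                [0.0, y0, 0.0],
                [L, y0, 0.0],
                [L, y1, 0.0],
                [0.0, y1, 0.0],
            ]
        ),
        seg_head=[0, 2],
        seg_tail=[1, 3],
        diameter=[d, d],
    )
    bc = _base_bc([0, 2], [1, 3], dp, hematocrit, oxygen)
    return net, bc
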