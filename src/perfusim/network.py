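"""Vascular network data model, I/O, classification and re-segmentation.

The microvascular bed is represented as a 1D graph of straight cylindrical
segments (chords) between 3D nodes.  Coordinates are in micrometres with a
right-handed frame in which ``z`` is cortical depth: ``z = 0`` at the pial
surface, increasing downward.  Positive flow on a segment runs from its
head node to its tail node.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
    IntegrityError,
    OutOfBoundsError,
    ParameterError,
    SchemaError,
    ValidationError,
)

VESSEL_CLASSES = (
    "pial_artery",
    "penetrating_arteriole",
    "capillary",
    "venule",
    "pial_vein",
    "pial",
    "penetrating",
    "",
)

#: Diameter below which a vessel counts as a capillary (strict inequality).
CAPILLARY_CUTOFF_UM = 6.0


@dataclass
class VascularNetwork:
    """Node/segment graph of the microvasculature.

    Attributes
    ----------
    node_xyz:
        ``(n_nodes, 3)`` positions in µm.
    seg_head, seg_tail:
        0-based node indices per segment; positive flow runs head -> tail.
    diameter:
        Segment diameters in µm.  May be 0 only for occluded segments.
    vessel_class:
        Per-segment class label (see :data:`VESSEL_CLASSES`; ``""`` = unset).
    occluded:
        Per-segment occlusion flag (occluded segments carry no flow).
    node_labels, seg_labels:
        Original file labels; internal indices are always contiguous ints.
    """

    node_xyz: np.ndarray
    seg_head: np.ndarray
    seg_tail: np.ndarray
    diameter: np.ndarray
    vessel_class: np.ndarray = None
    occluded: np.ndarray = None
    node_labels: np.ndarray = None
    seg_labels: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.node_xyz = np.asarray(self.node_xyz, dtype=float).reshape(-1, 3)
        self.seg_head = np.asarray(self.seg_head, dtype=np.int64).ravel()
        self.seg_tail = np.asarray(self.seg_tail, dtype=np.int64).ravel()
        self.diameter = np.asarray(self.diameter, dtype=float).ravel()
        n = self.n_segments
        if self.vessel_class is None:
            self.vessel_class = np.full(n, "", dtype=object)
        else:
            self.vessel_class = np.asarray(self.vessel_class, dtype=object).ravel()
        if self.occluded is None:
            self.occluded = np.zeros(n, dtype=bool)
        else:
            self.occluded = np.asarray(self.occluded, dtype=bool).ravel()
        if self.node_labels is None:
            self.node_labels = np.arange(self.n_nodes)
        else:
            self.node_labels = np.asarray(self.node_labels).ravel()
        if self.seg_labels is None:
            self.seg_labels = np.arange(n)
        else:
            self.seg_labels = np.asarray(self.seg_labels).ravel()

    # -- basic measures -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.node_xyz.shape[0]

    @property
    def n_segments(self) -> int:
        return self.seg_head.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        """Euclidean chord lengths in µm."""
        d = self.node_xyz[self.seg_head] - self.node_xyz[self.seg_tail]
        return np.linalg.norm(d, axis=1)

    @property
    def vascular_volume(self) -> float:
        """Total cylinder volume Σ (π/4) d² L in µm³."""
        return float(np.sum(np.pi / 4.0 * self.diameter**2 * self.lengths))

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(
            node_xyz=self.node_xyz.copy(),
            seg_head=self.seg_head.copy(),
            seg_tail=self.seg_tail.copy(),
            diameter=self.diameter.copy(),
            vessel_class=self.vessel_class.copy(),
            occluded=self.occluded.copy(),
            node_labels=self.node_labels.copy(),
            seg_labels=self.seg_labels.copy(),
            metadata=dict(self.metadata),
        )

    def validate(self) -> None:
        """Check structural invariants; raise on violation."""
        n = self.n_nodes
        if self.seg_head.size != self.seg_tail.size or self.seg_head.size != self.diameter.size:
            raise IntegrityError("segment arrays have inconsistent sizes")
        for arr, name in ((self.seg_head, "head"), (self.seg_tail, "tail")):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise IntegrityError(f"segment {name} references a node outside [0, {n})")
        if np.any(self.seg_head == self.seg_tail):
            raise ValidationError("segment with identical head and tail node")
        if np.any(self.lengths <= 0):
            raise ValidationError("segment with nonpositive length")
        bad_d = (self.diameter < 0) | ((self.diameter == 0) & ~self.occluded)
        if np.any(bad_d):
            raise ValidationError(
                "negative diameter, or zero diameter on a non-occluded segment"
            )

    # -- graph helpers ---------------------------------------------------

    def adjacency(self, include_occluded: bool = False) -> sp.csr_matrix:
        """Symmetric node adjacency (1 where a segment joins two nodes)."""
        keep = np.ones(self.n_segments, bool) if include_occluded else ~self.occluded
        h, t = self.seg_head[keep], self.seg_tail[keep]
        ones = np.ones(h.size)
        a = sp.coo_matrix(
            (np.r_[ones, ones], (np.r_[h, t], np.r_[t, h])),
            shape=(self.n_nodes, self.n_nodes),
        )
        return a.tocsr()


@dataclass
class BoundaryConditionSet:
    """Dirichlet/Neumann data for the flow, hematocrit and oxygen problems.

    ``pressure`` maps node index -> p̄ (mmHg); ``flow`` maps node index -> q̄
    (µm³/s, positive = injection).  ``inlet_hematocrit`` and ``inlet_oxygen``
    carry h̄ and c̄v at inflow boundary nodes.  ``tissue_dirichlet`` maps a
    linear cell index on the *finest* grid to a fixed tissue tension (mmHg).
    """

    pressure: dict = field(default_factory=dict)
    flow: dict = field(default_factory=dict)
    inlet_hematocrit: dict = field(default_factory=dict)
    inlet_oxygen: dict = field(default_factory=dict)
    tissue_dirichlet: dict = field(default_factory=dict)

    def validate(self, net: VascularNetwork | None = None) -> None:
        if not self.pressure:
            raise ValidationError("at least one pressure Dirichlet node is required")
        for h in self.inlet_hematocrit.values():
            if not (0.0 < h < 1.0):
                raise ValidationError(f"inlet hematocrit {h} outside (0, 1)")
        for c in self.inlet_oxygen.values():
            if c < 0:
                raise ValidationError(f"negative inlet oxygen tension {c}")
        if set(self.pressure) & set(self.flow):
            raise ValidationError("a node cannot carry both pressure and flow BCs")
        if net is not None:
            for n in list(self.pressure) + list(self.flow):
                if not (0 <= n < net.n_nodes):
                    raise IntegrityError(f"boundary condition on unknown node {n}")

    def copy(self) -> "BoundaryConditionSet":
        return BoundaryConditionSet(
            pressure=dict(self.pressure),
            flow=dict(self.flow),
            inlet_hematocrit=dict(self.inlet_hematocrit),
            inlet_oxygen=dict(self.inlet_oxygen),
            tissue_dirichlet=dict(self.tissue_dirichlet),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NODE_COLS = ["id", "x_um", "y_um", "z_um", "bc_type", "bc_value"]
_SEG_COLS = ["id", "node_head", "node_tail", "diameter_um", "occluded"]


def write_network(net: VascularNetwork, path, dialect: str = "csv",
                  bc: BoundaryConditionSet | None = None) -> None:
    """Write a network (and optional boundary data) to CSV or JSON.

    CSV dialect writes ``<path>/nodes.csv`` and ``<path>/segments.csv``;
    JSON writes a single document at ``path``.
    """
    bc = bc or BoundaryConditionSet()
    bc_type = np.full(net.n_nodes, "none", dtype=object)
    bc_value = np.zeros(net.n_nodes)
    for n, p in bc.pressure.items():
        bc_type[n], bc_value[n] = "pressure", p
    for n, q in bc.flow.items():
        bc_type[n], bc_value[n] = "flow", q

    nodes = pd.DataFrame(
        {
            "id": net.node_labels,
            "x_um": net.node_xyz[:, 0],
            "y_um": net.node_xyz[:, 1],
            "z_um": net.node_xyz[:, 2],
            "bc_type": bc_type,
            "bc_value": bc_value,
        }
    )
    segs = pd.DataFrame(
        {
            "id": net.seg_labels,
            "node_head": net.node_labels[net.seg_head],
            "node_tail": net.node_labels[net.seg_tail],
            "diameter_um": net.diameter,
            "occluded": net.occluded.astype(int),
        }
    )
    if dialect == "csv":
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        nodes.to_csv(path / "nodes.csv", index=False)
        segs.to_csv(path / "segments.csv", index=False)
    elif dialect == "json":
        doc = {
            "nodes": nodes.to_dict(orient="records"),
            "segments": segs.to_dict(orient="records"),
            "boundary_conditions": {
                "inlet_hematocrit": {str(k): v for k, v in bc.inlet_hematocrit.items()},
                "inlet_oxygen": {str(k): v for k, v in bc.inlet_oxygen.items()},
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))
    else:
        raise ParameterError(f"unknown dialect {dialect!r} (use 'csv' or 'json')")


def read_network(path, dialect: str = "csv"):
    """Read a network written by :func:`write_network`.

    Returns ``(VascularNetwork, BoundaryConditionSet)``.  Node ids are
    re-indexed to contiguous 0-based integers; original ids are preserved
    as labels.
    """
    if dialect == "csv":
        path = Path(path)
        nodes = pd.read_csv(path / "nodes.csv")
        segs = pd.read_csv(path / "segments.csv")
        extra_bc = {}
    elif dialect == "json":
        doc = json.loads(Path(path).read_text())
        nodes = pd.DataFrame(doc["nodes"])
        segs = pd.DataFrame(doc["segments"])
        extra_bc = doc.get("boundary_conditions", {})
    else:
        raise ParameterError(f"unknown dialect {dialect!r} (use 'csv' or 'json')")

    for col in _NODE_COLS[:4]:
        if col not in nodes.columns:
            raise SchemaError(f"nodes table missing column {col!r}")
    for col in _SEG_COLS[:4]:
        if col not in segs.columns:
            raise SchemaError(f"segments table missing column {col!r}")

    labels = nodes["id"].to_numpy()
    index_of = {lab: i for i, lab in enumerate(labels)}
    if len(index_of) != len(labels):
        raise IntegrityError("duplicate node ids in nodes table")

    def _lookup(col):
        out = np.empty(len(segs), dtype=np.int64)
        for i, lab in enumerate(segs[col].to_numpy()):
            if lab not in index_of:
                raise IntegrityError(f"segment references unknown node id {lab!r}")
            out[i] = index_of[lab]
        return out

    net = VascularNetwork(
        node_xyz=nodes[["x_um", "y_um", "z_um"]].to_numpy(float),
        seg_head=_lookup("node_head"),
        seg_tail=_lookup("node_tail"),
        diameter=segs["diameter_um"].to_numpy(float),
        occluded=segs["occluded"].to_numpy().astype(bool)
        if "occluded" in segs.columns
        else None,
        node_labels=labels,
        seg_labels=segs["id"].to_numpy(),
    )
    net.validate()

    bc = BoundaryConditionSet()
    if "bc_type" in nodes.columns:
        for i, (t, v) in enumerate(zip(nodes["bc_type"], nodes["bc_value"])):
            if t == "pressure":
                bc.pressure[i] = float(v)
            elif t == "flow":
                bc.flow[i] = float(v)
    for key, target in (
        ("inlet_hematocrit", bc.inlet_hematocrit),
        ("inlet_oxygen", bc.inlet_oxygen),
    ):
        for k, v in extra_bc.get(key, {}).items():
            target[index_of.get(int(k), int(k))] = float(v)
    return net, bc


# ---------------------------------------------------------------------------
# Incidence
# ---------------------------------------------------------------------------

def incidence_matrix(net: VascularNetwork) -> sp.csr_matrix:
    """Arc-node incidence C1 (nArcs × nPts): +1 at head, −1 at tail.

    With this orientation, positive segment flow runs head -> tail and the
    Kirchhoff balance at interior nodes reads ``C1.T @ f = 0``.
    """
    rows = np.repeat(np.arange(net.n_segments), 2)
    cols = np.empty(2 * net.n_segments, dtype=np.int64)
    cols[0::2] = net.seg_head
    cols[1::2] = net.seg_tail
    vals = np.tile([1.0, -1.0], net.n_segments)
    return sp.csr_matrix((vals, (rows, cols)), shape=(net.n_segments, net.n_nodes))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_vessels(
    net: VascularNetwork,
    surface_depth: float,
    capillary_cutoff: float = CAPILLARY_CUTOFF_UM,
    inlet_nodes=None,
    outlet_nodes=None,
) -> VascularNetwork:
    """Assign vessel classes by diameter, depth and inlet/outlet rooting.

    Segments with ``d < capillary_cutoff`` (strict) are capillaries.
    Non-capillaries with both endpoints shallower than ``surface_depth``
    are pial, the rest penetrating.  If inlet/outlet node sets are given,
    the arterial/venous sides are resolved by traversing the non-capillary
    subgraph from those roots (a simplification of Strahler-order labeling
    used on empirical reconstructions); otherwise only
    {capillary, pial, penetrating} are assigned, with a warning.
    """
    net = net.copy()
    z = net.node_xyz[:, 2]
    is_cap = net.diameter < capillary_cutoff
    both_shallow = (z[net.seg_head] < surface_depth) & (z[net.seg_tail] < surface_depth)

    cls = np.full(net.n_segments, "", dtype=object)
    cls[is_cap] = "capillary"
    cls[~is_cap & both_shallow] = "pial"
    cls[~is_cap & ~both_shallow] = "penetrating"

    if inlet_nodes is None or outlet_nodes is None:
        warnings.warn(
            "no inlet/outlet labels: artery/vein sides not resolved "
            "(classes limited to capillary/pial/penetrating)",
            stacklevel=2,
        )
        net.vessel_class = cls
        return net

    # traverse the non-capillary subgraph from the labeled roots
    noncap = ~is_cap
    n = net.n_nodes
    h, t = net.seg_head[noncap], net.seg_tail[noncap]
    ones = np.ones(h.size)
    adj = sp.coo_matrix(
        (np.r_[ones, ones], (np.r_[h, t], np.r_[t, h])), shape=(n, n)
    ).tocsr()

    def _reach(roots):
        mask = np.zeros(n, bool)
        roots = [r for r in roots if 0 <= r < n]
        if not roots:
            return mask
        order = sp.csgraph.breadth_first_order(
            adj, roots[0], directed=False, return_predecessors=False
        )
        mask[order] = True
        for r in roots[1:]:
            if not mask[r]:
                order = sp.csgraph.breadth_first_order(
                    adj, r, directed=False, return_predecessors=False
                )
                mask[order] = True
        return mask

    arterial = _reach(list(inlet_nodes))
    venous = _reach(list(outlet_nodes))
    for s in np.flatnonzero(noncap):
        a = arterial[net.seg_head[s]] or arterial[net.seg_tail[s]]
        v = venous[net.seg_head[s]] or venous[net.seg_tail[s]]
        if a and not v:
            cls[s] = "pial_artery" if cls[s] == "pial" else "penetrating_arteriole"
        elif v and not a:
            cls[s] = "pial_vein" if cls[s] == "pial" else "venule"
        # ambiguous or unreachable: keep the geometric class
    net.vessel_class = cls
    return net


# ---------------------------------------------------------------------------
# Partitioning (re-segmentation)
# ---------------------------------------------------------------------------

def partition_segments(net: VascularNetwork, grid) -> VascularNetwork:
    """Bisect segments until every chord spans at most two adjacent voxels.

    Endpoints must land in the same voxel or in voxels whose index
    difference is at most one in every axis (Chebyshev distance ≤ 1).
    Child segments inherit diameter, class and occlusion from the parent;
    new nodes lie on the parent chord, so total length is conserved
    exactly up to floating point.  ``metadata['parent_segment']`` maps each
    child to the original segment index.
    """
    lo, hi = grid.bounds
    xyz = net.node_xyz
    if np.any(xyz < lo - 1e-9) or np.any(xyz > hi + 1e-9):
        out = np.flatnonzero(
            np.any(xyz[net.seg_head] < lo - 1e-9, axis=1)
            | np.any(xyz[net.seg_head] > hi + 1e-9, axis=1)
            | np.any(xyz[net.seg_tail] < lo - 1e-9, axis=1)
            | np.any(xyz[net.seg_tail] > hi + 1e-9, axis=1)
        )
        raise OutOfBoundsError(f"network extends outside grid; segments {out.tolist()}")

    nodes = [tuple(p) for p in xyz]
    new_xyz = list(map(np.asarray, xyz))
    heads, tails, parents = [], [], []

    for s in range(net.n_segments):
        # stack of (head_idx, tail_idx, depth)
        stack = [(int(net.seg_head[s]), int(net.seg_tail[s]), 0)]
        while stack:
            a, b, depth = stack.pop()
            ia = grid.point_to_index(new_xyz[a])
            ib = grid.point_to_index(new_xyz[b])
            if np.max(np.abs(ia - ib)) <= 1:
                heads.append(a)
                tails.append(b)
                parents.append(s)
                continue
            if depth >= 64:
                raise ValidationError(
                    f"segment {s} needed more than 64 bisection rounds: "
                    "grid spacing is too small relative to the network scale"
                )
            mid = 0.5 * (new_xyz[a] + new_xyz[b])
            new_xyz.append(mid)
            m = len(new_xyz) - 1
            stack.append((m, b, depth + 1))
            stack.append((a, m, depth + 1))

    parents = np.asarray(parents, dtype=np.int64)
    out = VascularNetwork(
        node_xyz=np.asarray(new_xyz),
        seg_head=np.asarray(heads, dtype=np.int64),
        seg_tail=np.asarray(tails, dtype=np.int64),
        diameter=net.diameter[parents],
        vessel_class=net.vessel_class[parents],
        occluded=net.occluded[parents],
        metadata=dict(net.metadata),
    )
    out.metadata["parent_segment"] = parents
    out.metadata["n_original_nodes"] = net.n_nodes
    return out
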