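"""Field and network export: legacy ASCII VTK, raw + header, CSV slices.

Cell-centered scalar fields are written as VTK structured points with
CELL_DATA, as a flat binary array with a JSON sidecar documenting
dimensions/spacing/origin/dtype/linearization (x-fastest), or as one CSV
per k-layer.  Networks export as VTK polydata with per-segment cell data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .voxels import CartesianGrid

LINEARIZATION = "x-fastest: lin = i + nx*j + nx*ny*k"


def export_field(grid: CartesianGrid, arrays: dict, path, format: str = "vtk_image"):
    """Write one or more cell-centered fields in the requested format."""
    if format == "vtk_image":
        return write_vtk_image(grid, arrays, path)
    if format == "raw+header":
        return write_raw_with_header(grid, arrays, path)
    if format == "csv_slices":
        return write_csv_slices(grid, arrays, path)
    raise ParameterError(
        f"unsupported format {format!r}; use vtk_image, raw+header or csv_slices"
    )


def write_vtk_image(grid: CartesianGrid, arrays: dict, path):
    """Legacy ASCII VTK structured points with cell data."""
    nx, ny, nz = grid.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "perfusim field export",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {grid.origin[0]:.9g} {grid.origin[1]:.9g} {grid.origin[2]:.9g}",
        f"SPACING {grid.spacing:.9g} {grid.spacing:.9g} {grid.spacing:.9g}",
        f"CELL_DATA {grid.n_cells}",
    ]
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        flat = arr.reshape(-1, order="F")
        if np.issubdtype(arr.dtype, np.integer):
            lines.append(f"SCALARS {name} int 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(" ".join(map(str, chunk)) for chunk in _chunks(flat, 12))
        else:
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(
                " ".join(f"{v:.9g}" for v in chunk) for chunk in _chunks(flat, 8)
            )
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def _chunks(arr, n):
    for i in range(0, len(arr), n):
        yield arr[i:i + n]


def write_raw_with_header(grid: CartesianGrid, arrays: dict, path):
    """Flat float64 binary per array + one JSON sidecar; lossless round trip."""
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "dimensions": list(grid.shape),
        "spacing_um": grid.spacing,
        "origin_um": list(grid.origin),
        "linearization": LINEARIZATION,
        "arrays": {},
    }
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        raw_path = base.with_suffix(f".{name}.raw")
        arr.reshape(-1, order="F").astype(arr.dtype).tofile(raw_path)
        header["arrays"][name] = {"dtype": str(arr.dtype), "file": raw_path.name}
    hdr = base.with_suffix(".header.json")
    hdr.write_text(json.dumps(header, indent=1))
    return hdr


def read_raw_with_header(header_path):
    """Round-trip reader for :func:`write_raw_with_header`."""
    hdr_path = Path(header_path)
    header = json.loads(hdr_path.read_text())
    nx, ny, nz = header["dimensions"]
    grid = CartesianGrid(tuple(header["origin_um"]), header["spacing_um"], (nx, ny, nz))
    arrays = {}
    for name, meta in header["arrays"].items():
        flat = np.fromfile(hdr_path.parent / meta["file"], dtype=meta["dtype"])
        arrays[name] = flat.reshape((nx, ny, nz), order="F")
    return grid, arrays


def write_csv_slices(grid: CartesianGrid, arrays: dict, path):
    """One CSV per k-layer per array (count = nz)."""
    base = Path(path)
    base.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        for k in range(grid.shape[2]):
            p = base / f"{name}_k{k:04d}.csv"
            pd.DataFrame(arr[:, :, k]).to_csv(p, index=False, header=False)
            written.append(p)
    return written


def write_vtk_polylines(net, path, cell_data: dict | None = None):
    """Network centerlines as legacy ASCII VTK polydata.

    Diameter and vessel class index are always attached; extra per-segment
    arrays may be passed via ``cell_data``.
    """
    classes = sorted(set(net.vessel_class.tolist()))
    class_index = {c: i for i, c in enumerate(classes)}
    lines = [
        "# vtk DataFile Version 3.0",
        "perfusim network export: " + ";".join(f"{i}={c or 'unset'}" for c, i in class_index.items()),
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {net.n_nodes} float",
    ]
    lines.extend(
        f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in net.node_xyz
    )
    lines.append(f"LINES {net.n_segments} {3 * net.n_segments}")
    lines.extend(
        f"2 {h} {t}" for h, t in zip(net.seg_head, net.seg_tail)
    )
    data = {"diameter_um": net.diameter.astype(float),
            "vessel_class": np.asarray([class_index[c] for c in net.vessel_class])}
    if cell_data:
        data.update({k: np.asarray(v) for k, v in cell_data.items()})
    lines.append(f"CELL_DATA {net.n_segments}")
    for name, arr in data.items():
        if np.issubdtype(arr.dtype, np.integer):
            lines.append(f"SCALARS {name} int 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(" ".join(map(str, chunk)) for chunk in _chunks(arr, 12))
        else:
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(" ".join(f"{v:.9g}" for v in chunk) for chunk in _chunks(arr, 8))
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
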