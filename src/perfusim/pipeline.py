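"""End-to-end pipeline: network → flow → masking → oxygen → analyses.

Every stage error is re-raised with the stage name; all artifacts (fields,
tables, audits, the resolved config) land in the run directory.  Reruns
with an equal effective config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, export, hemodynamics, oxygen, solvers, synthetic, voxels
from .config import RunConfig
from .errors import PerfusimError
from .network import classify_vessels, partition_segments, read_network

log = logging.getLogger("perfusim")


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            log.info("stage %s", name)
            try:
                return fn(*a, **kw)
            except PerfusimError as err:
                raise type(err)(f"[stage {name}] {err}") from err
        return wrapper
    return deco


@_stage("network")
def _load_network(config: RunConfig):
    if config.network_path is not None:
        net, bc = read_network(config.network_path, config.network_dialect)
        if all(c == "" for c in net.vessel_class):
            inlets = [n for n in bc.pressure if n in bc.inlet_hematocrit]
            outlets = [n for n in bc.pressure if n not in bc.inlet_hematocrit]
            net = classify_vessels(
                net, surface_depth=config.surface_depth_um,
                inlet_nodes=inlets, outlet_nodes=outlets,
            )
        return net, bc
    return synthetic.generate_cortex_network(
        extent=config.extent_um,
        target_density=config.target_density_per_mm3,
        n_penetrating_pairs=config.n_penetrating_pairs,
        pressure_drop=config.pressure_drop_mmhg,
        inlet_hematocrit=config.inlet_hematocrit,
        inlet_oxygen=config.inlet_oxygen_mmhg,
        seed=config.seed,
    )


def run_pipeline(config: RunConfig, out_dir=None) -> Path:
    """Execute the full simulation described by ``config``.

    Returns the run directory containing per-segment/per-node CSVs, the
    mass audits, the analysis tables, exported fields and the resolved
    configuration.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.resolved.yaml")

    net, bc = _load_network(config)

    if config.scenario != "young":
        net, bc = analysis.aging_scenario(
            net, bc,
            occlusion_fraction=config.occlusion_fraction,
            hematocrit_factor=config.hematocrit_factor,
            seed=config.seed,
            mode=RunConfig.SCENARIO_MODES[config.scenario],
        )

    flow = _solve_flow(net, bc, config)
    flow_audit = hemodynamics.flow_mass_audit(net, bc, flow.f)

    grid = voxels.build_grid(config.extent_um, shape=config.grid_cells)
    part = _partition(net, grid)
    pflow = _map_flow(part, flow)

    params = oxygen.PhysiologyParams.from_per_ms(
        config.metabolic_rate_per_ms,
        D=config.diffusivity_um2_s,
        U=config.permeability_um2_s,
        w=config.endothelial_thickness_um,
        inlet_oxygen=config.inlet_oxygen_mmhg,
        beta_model=config.beta_model,
        h_ref=config.inlet_hematocrit,
    )
    sol = _solve_oxygen(part, grid, pflow, params, bc, config)
    audit = analysis.oxygen_mass_audit(sol.system, sol, flow_audit)

    _write_outputs(out, config, net, bc, flow, sol, audit)
    return out


@_stage("flow")
def _solve_flow(net, bc, config: RunConfig):
    return hemodynamics.fixed_point_hemodynamics(
        net, bc,
        viscosity_model=config.viscosity_model,
        skimming_model=config.skimming_model,
        tol=config.flow_tol,
        max_iter=config.flow_max_iter,
    )


@_stage("partition")
def _partition(net, grid):
    return partition_segments(net, grid)


def _map_flow(part, flow):
    """Inherit converged per-segment f, h onto the partitioned children."""
    parents = part.metadata["parent_segment"]
    return hemodynamics.FlowSolution(
        f=flow.f[parents],
        p=np.zeros(part.n_nodes),
        h=flow.h[parents],
        iterations=flow.iterations,
        residual=flow.residual,
    )


@_stage("oxygen")
def _solve_oxygen(part, grid, pflow, params, bc, config: RunConfig):
    return solvers.solve_oxygen(
        part, grid, pflow, params, bc,
        rtol=config.oxygen_rtol,
        levels=config.hierarchy_levels,
        preconditioner=config.preconditioner,
    )


@_stage("output")
def _write_outputs(out: Path, config: RunConfig, net, bc, flow, sol, audit):
    pd.DataFrame(
        {
            "id": net.seg_labels,
            "f_nl_per_s": flow.f / hemodynamics.NL_PER_S,
            "h": flow.h,
            "vessel_class": net.vessel_class,
            "occluded": net.occluded.astype(int),
        }
    ).to_csv(out / "segments_flow.csv", index=False)
    pd.DataFrame({"id": net.node_labels, "p_mmHg": flow.p}).to_csv(
        out / "nodes_pressure.csv", index=False
    )
    (out / "mass_audit.json").write_text(json.dumps(audit.as_dict(), indent=1))

    field = sol.reconstructed_field()
    grid = sol.system.grid
    export.export_field(
        grid,
        {"pO2_mmHg": field, "label": sol.system.labels.label.astype(np.int32)},
        out / ("field.vtk" if config.field_format == "vtk_image" else "field"),
        format=config.field_format,
    )

    fractions = analysis.hypoxic_fraction(
        sol, thresholds=config.hypoxia_thresholds_mmhg,
        roi=config.roi_box_um if config.roi_box_um is None
        else (tuple(config.roi_box_um[:3]), tuple(config.roi_box_um[3:])),
    )
    pd.DataFrame(
        [
            {
                "threshold_mmHg": thr,
                "fraction": rec["fraction"],
                "n_components": rec["n_components"],
            }
            for thr, rec in fractions.items()
        ]
    ).to_csv(out / "hypoxic_fractions.csv", index=False)

    maps = analysis.depth_plane_map(sol, depths=config.depth_planes_um)
    for depth, (k, plane) in maps.items():
        pd.DataFrame(plane).to_csv(
            out / f"depth_{int(depth):04d}um_k{k}.csv", index=False, header=False
        )

    summary = {
        "flow_iterations": flow.iterations,
        "oxygen_iterations": sol.iterations,
        "oxygen_residual": sol.residual,
        "n_segments": int(net.n_segments),
        "n_nodes": int(net.n_nodes),
        "grid_shape": list(grid.shape),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
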