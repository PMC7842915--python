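import numpy as np
import pytest

import perfusim as pf


@pytest.fixture(scope="session")
def cortex():
    """Seeded synthetic cortical network + BCs (the standard desk-scale case)."""
    net, bc = pf.generate_cortex_network(extent=(300.0, 300.0, 300.0), seed=1)
    return net, bc


@pytest.fixture(scope="session")
def cortex_flow(cortex):
    net, bc = cortex
    return pf.fixed_point_hemodynamics(net, bc)


@pytest.fixture
def single_vessel():
    return pf.make_fixture("single_vessel", L=100.0, d=10.0, dp=1.0)


@pytest.fixture
def y_bifurcation():
    return pf.make_fixture("y_bifurcation")


def map_flow_to_partition(part, flow):
    """Inherit converged per-segment flow/hematocrit onto partitioned children."""
    parents = part.metadata["parent_segment"]
    return pf.FlowSolution(
        f=flow.f[parents],
        p=np.zeros(part.n_nodes),
        h=flow.h[parents],
        iterations=flow.iterations,
        residual=flow.residual,
    )


def solve_cortex_oxygen(net, bc, flow, n_cells, extent=(300.0, 300.0, 300.0),
                        params=None, rtol=1e-12):
    """Partition, mask, assemble and solve the coupled oxygen problem."""
    from perfusim.oxygen import split_solution

    grid = pf.build_grid(extent, shape=(n_cells,) * 3)
    part = pf.partition_segments(net, grid)
    labels = pf.label_mesh(grid, part, w=1.0)
    pflow = map_flow_to_partition(part, flow)
    params = params or pf.PhysiologyParams()
    system = pf.assemble_coupled_system(part, grid, labels, pflow.f, pflow.h,
                                        params, bc)
    x, rec = pf.solve_sparse(system.A, system.b, rtol=rtol,
                             block_split=system.n_vascular)
    return split_solution(system, x, rec.iterations, rec.residual)
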