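import numpy as np
import pytest
import scipy.sparse as sp

import perfusim as pf
from perfusim.oxygen import (
    assemble_convection,
    assemble_diffusion,
    assemble_mass_transfer,
    assemble_reaction,
    mass_transfer_couplings,
    split_solution,
    tissue_index_map,
)
from perfusim.voxels import INTERIOR

from conftest import map_flow_to_partition, solve_cortex_oxygen


def small_params(**kw):
    """Moderate consumption so tissue fields keep dynamic range in fixtures."""
    defaults = dict(k_met=10.0)
    defaults.update(kw)
    return pf.PhysiologyParams(**defaults)


class TestConvection:
    def test_zero_flow_gives_zero_operator(self, single_vessel):
        net, _ = single_vessel
        Mc = assemble_convection(net, [0.0], [0.35])
        assert Mc.nnz == 0

    def test_single_segment_downwind_pattern(self, single_vessel):
        net, _ = single_vessel
        Mc = assemble_convection(net, [2.0], [0.35],
                                 pf.PhysiologyParams(beta_model="unit")).toarray()
        # flux enters the tail row from the head (the only off-diagonal);
        # the head row is a boundary inlet with no inflow, hence empty
        np.testing.assert_allclose(Mc, [[0.0, 0.0], [2.0, -2.0]])

    def test_asymmetric_under_flow(self, cortex, cortex_flow):
        net, _ = cortex
        Mc = assemble_convection(net, cortex_flow.f, cortex_flow.h)
        assert (Mc != Mc.T).nnz > 0

    def test_interior_row_sums_vanish(self, cortex, cortex_flow):
        net, bc = cortex
        Mc = assemble_convection(net, cortex_flow.f, cortex_flow.h)
        sums = np.asarray(Mc.sum(axis=1)).ravel()
        interior = np.ones(net.n_nodes, bool)
        interior[list(bc.pressure)] = False
        assert np.max(np.abs(sums[interior])) <= 1e-9 * np.max(np.abs(Mc.data))


class TestMassTransfer:
    def grid_labels(self, cortex):
        net, _ = cortex
        grid = pf.build_grid((300.0, 300.0, 300.0), shape=(16, 16, 16))
        part = pf.partition_segments(net, grid)
        return part, grid, pf.label_mesh(grid, part, w=1.0)

    def test_zero_permeability_decouples(self, cortex):
        part, grid, labels = self.grid_labels(cortex)
        params = pf.PhysiologyParams(U=1e-300)
        _, Gamma1 = assemble_mass_transfer(part, labels, params)
        assert np.max(Gamma1.diagonal()) <= 1e-290

    def test_even_split_conductances(self):
        net = pf.VascularNetwork(
            node_xyz=np.array([[10.0, 20.0, 20.0], [34.0, 20.0, 20.0]]),
            seg_head=[0], seg_tail=[1], diameter=[8.0],
        )
        grid = pf.build_grid((40.0, 40.0, 40.0), spacing=2.0)
        part = pf.partition_segments(net, grid)
        params = pf.PhysiologyParams()
        labels = pf.label_mesh(grid, part, w=1.0)
        node, cell, g = mass_transfer_couplings(part, labels, params)
        surface = np.pi * part.diameter * part.lengths
        # couplings are appended segment by segment, endothelial cells first
        # where present, otherwise the single fallback host
        pos = 0
        for s in range(part.n_segments):
            n = labels.seg_endo_cells[s].size
            if n:
                expected = params.U * (surface[s] / n) / params.w
                np.testing.assert_allclose(g[pos:pos + n], expected, rtol=1e-12)
                np.testing.assert_array_equal(np.sort(cell[pos:pos + n]),
                                              np.sort(labels.seg_endo_cells[s]))
                pos += n
            elif labels.seg_fallback_cell[s] >= 0:
                expected = params.U * surface[s] / params.w
                assert g[pos] == pytest.approx(expected, rel=1e-12)
                pos += 1
        assert pos == g.size

    def test_exchange_block_symmetric(self, cortex):
        part, grid, labels = self.grid_labels(cortex)
        C3, Gamma1 = assemble_mass_transfer(part, labels, pf.PhysiologyParams())
        E = (C3.T @ Gamma1 @ C3).tocsr()
        assert (abs(E - E.T)).max() == 0.0


class TestDiffusionReaction:
    def empty_labels(self, n=6):
        grid = pf.build_grid((float(n), float(n), float(n)), spacing=1.0)
        net = pf.VascularNetwork(
            node_xyz=np.array([[0.5, 0.5, 0.5], [1.5, 1.5, 1.5]]),
            seg_head=[0], seg_tail=[1], diameter=[0.0], occluded=[True],
        )
        return grid, pf.label_mesh(grid, net)

    def test_interior_rows_have_seven_nonzeros(self):
        grid, labels = self.empty_labels()
        Md = assemble_diffusion(grid, labels, 1800.0).tocsr()
        tissue, _ = tissue_index_map(labels)
        ijk = grid.unravel(tissue)
        interior = np.all((ijk >= 1) & (ijk <= np.asarray(grid.shape) - 2), axis=1)
        nnz = np.diff(Md.indptr)
        assert np.all(nnz[interior] == 7)

    def test_symmetry_and_null_space(self):
        grid, labels = self.empty_labels()
        Md = assemble_diffusion(grid, labels, 1800.0)
        assert (abs(Md - Md.T)).max() == 0.0
        c = np.full(Md.shape[0], 7.3)
        assert np.max(np.abs(Md @ c)) <= 1e-12 * 1800.0 * grid.spacing

    def test_reaction_diagonal_value(self):
        grid = pf.build_grid((20.0, 20.0, 20.0), spacing=5.0)
        net = pf.VascularNetwork(
            node_xyz=np.array([[0.5, 0.5, 0.5], [1.5, 1.5, 1.5]]),
            seg_head=[0], seg_tail=[1], diameter=[0.0], occluded=[True],
        )
        labels = pf.label_mesh(grid, net)
        R2 = assemble_reaction(grid, labels, 14.17e3)
        np.testing.assert_allclose(R2.diagonal(), 14.17e3 * 125.0, rtol=1e-12)
        assert R2.shape[0] == labels.tissue_cells.size


class TestCoupledSystem:
    def build(self, params=None):
        net, bc = pf.make_fixture("y_bifurcation")
        grid = pf.build_grid((200.0, 200.0, 40.0), spacing=10.0,
                             origin=(-10.0, -100.0, -20.0))
        part = pf.partition_segments(net, grid)
        labels = pf.label_mesh(grid, part, w=1.0)
        f, p = pf.solve_flow(net, bc)
        h = pf.solve_hematocrit(net, f, bc)
        flow = pf.FlowSolution(f=f, p=p, h=h, iterations=1, residual=0.0)
        pflow = map_flow_to_partition(part, flow)
        params = params or small_params()
        system = pf.assemble_coupled_system(part, grid, labels, pflow.f,
                                            pflow.h, params, bc)
        return part, grid, labels, pflow, params, bc, system

    def test_system_dimension(self):
        part, grid, labels, _, _, _, system = self.build()
        n_tissue = grid.n_cells - labels.n_interior
        assert system.n_unknowns == part.n_nodes + n_tissue

    def test_vascular_block_has_no_diffusion(self):
        _, _, _, _, _, _, system = self.build()
        n_v = system.n_vascular
        vasc = system.A[:n_v, :n_v] - system.Mc + system.exchange[:n_v, :n_v]
        # drop float cancellation noise relative to the block scale
        vasc.data[np.abs(vasc.data) < 1e-12 * np.abs(system.A.data).max()] = 0.0
        vasc.eliminate_zeros()
        # remaining entries are only the Dirichlet identity replacements
        rows = np.unique(vasc.tocoo().row)
        assert set(rows) <= set(system.inlet_nodes.tolist())

    def test_matches_unreduced_dense_oracle(self):
        """Monolithic dense solve keeping lumen cells explicit with identity
        (nearest-node) constraint rows must agree with the reduced system."""
        part, grid, labels, pflow, params, bc, system = self.build()
        x, rec = pf.solve_sparse(system.A, system.b, rtol=1e-12,
                                 block_split=system.n_vascular)
        n_v = part.n_nodes
        n_cells = grid.n_cells
        N = n_v + n_cells
        A = np.zeros((N, N))
        b = np.zeros(N)
        phi = pflow.f * params.beta(pflow.h)
        up = np.where(pflow.f >= 0, part.seg_head, part.seg_tail)
        dn = np.where(pflow.f >= 0, part.seg_tail, part.seg_head)
        # upwinded convection: inflow off-diagonals, row sums vanish
        # (boundary exit flux is implicit in the diagonal)
        for s in range(part.n_segments):
            A[dn[s], up[s]] += abs(phi[s])
        for v in range(n_v):
            A[v, v] -= A[v, :n_v].sum() - A[v, v]
        node_c, cell_c, g_c = system.couplings
        for nd, cl, g in zip(node_c, cell_c, g_c):
            A[nd, nd] -= g
            A[nd, n_v + cl] += g
            A[n_v + cl, n_v + cl] -= g
            A[n_v + cl, nd] += g
        flat = labels.label.reshape(-1, order="F")
        nx, ny, nz = grid.shape
        cond = params.D * grid.spacing
        for lin in range(n_cells):
            if flat[lin] == INTERIOR:
                A[n_v + lin, n_v + lin] = 1.0
                A[n_v + lin, labels.interior_node[lin]] = -1.0
                continue
            i, j, k = grid.unravel(lin)
            A[n_v + lin, n_v + lin] -= params.k_met * grid.cell_volume
            for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)):
                ni, nj, nk = i + di, j + dj, k + dk
                if not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz):
                    continue
                nlin = ni + nx * nj + nx * ny * nk
                if flat[nlin] == INTERIOR:
                    continue
                A[n_v + lin, n_v + lin] -= cond
                A[n_v + lin, n_v + nlin] += cond
        for v in system.inlet_nodes:
            A[v, :] = 0.0
            A[v, v] = 1.0
            b[v] = bc.inlet_oxygen[int(v)]
        dense = np.linalg.solve(A, b)
        np.testing.assert_allclose(x[:n_v], dense[:n_v], rtol=1e-9, atol=1e-12)
        tissue, _ = tissue_index_map(labels)
        np.testing.assert_allclose(x[n_v:], dense[n_v + tissue], rtol=1e-9,
                                   atol=1e-12)
        # lumen reconstruction matches the oracle's constraint rows
        sol = split_solution(system, x)
        field = sol.reconstructed_field().reshape(-1, order="F")
        np.testing.assert_allclose(field, dense[n_v:], rtol=1e-9, atol=1e-12)

    def test_pure_diffusion_constant_dirichlet(self):
        """U=0, k=0, one tissue Dirichlet cell: the field is that constant."""
        net, bc = pf.make_fixture("single_vessel", L=20.0, d=4.0)
        grid = pf.build_grid((40.0, 40.0, 40.0), spacing=5.0,
                             origin=(-10.0, -20.0, -20.0))
        part = pf.partition_segments(net, grid)
        labels = pf.label_mesh(grid, part, w=1.0)
        f, p = pf.solve_flow(net, bc)
        h = pf.solve_hematocrit(net, f, bc)
        pflow = map_flow_to_partition(
            part, pf.FlowSolution(f=f, p=p, h=h, iterations=1, residual=0.0)
        )
        params = pf.PhysiologyParams(U=1e-300, k_met=0.0)
        bc2 = bc.copy()
        bc2.tissue_dirichlet = {int(labels.tissue_cells[0]): 12.5}
        system = pf.assemble_coupled_system(part, grid, labels, pflow.f,
                                            pflow.h, params, bc2)
        x, _ = pf.solve_sparse(system.A, system.b, rtol=1e-12,
                               block_split=system.n_vascular)
        sol = split_solution(system, x)
        np.testing.assert_allclose(sol.ct, 12.5, rtol=1e-10)

    def test_discrete_maximum_principle(self):
        """0 ≤ c ≤ max inlet tension across randomized small networks."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            n_seg = 6
            pts = rng.uniform(5.0, 35.0, size=(n_seg + 1, 3))
            net = pf.VascularNetwork(
                node_xyz=pts,
                seg_head=np.arange(n_seg),
                seg_tail=np.arange(1, n_seg + 1),
                diameter=rng.uniform(3.0, 8.0, size=n_seg),
            )
            cbar = float(rng.uniform(20.0, 80.0))
            bc = pf.BoundaryConditionSet(
                pressure={0: float(rng.uniform(5.0, 50.0)), n_seg: 0.0},
                inlet_hematocrit={0: 0.35},
                inlet_oxygen={0: cbar},
            )
            grid = pf.build_grid((40.0, 40.0, 40.0), spacing=4.0)
            part = pf.partition_segments(net, grid)
            labels = pf.label_mesh(grid, part, w=1.0)
            f, p = pf.solve_flow(net, bc)
            h = pf.solve_hematocrit(net, f, bc)
            flow = pf.FlowSolution(f=f, p=p, h=h, iterations=1, residual=0.0)
            pflow = map_flow_to_partition(part, flow)
            params = small_params(k_met=float(rng.uniform(0.0, 50.0)))
            system = pf.assemble_coupled_system(part, grid, labels, pflow.f,
                                                pflow.h, params, bc)
            x, _ = pf.solve_sparse(system.A, system.b, rtol=1e-11,
                                   block_split=system.n_vascular)
            assert x.min() >= -1e-9 * cbar
            assert x.max() <= cbar * (1 + 1e-9)


class TestAnalyticLimit:
    def test_slab_cosh_second_order_convergence(self):
        """1D diffusion-reaction slab vs the cosh closed form."""
        D, k, L, c0 = 1800.0, 0.72, 100.0, 50.0
        lam = np.sqrt(k / D)
        errors = []
        for n in (16, 32, 64):
            grid = pf.build_grid((L, 2 * L / n, 2 * L / n), shape=(n, 2, 2))
            net = pf.VascularNetwork(
                node_xyz=np.array([[1.0, 1.0, 1.0], [2.0, 1.0, 1.0]]),
                seg_head=[0], seg_tail=[1], diameter=[0.0], occluded=[True],
            )
            labels = pf.label_mesh(grid, net)
            A = (assemble_diffusion(grid, labels, D)
                 - assemble_reaction(grid, labels, k)).tolil()
            tissue, index = tissue_index_map(labels)
            b = np.zeros(A.shape[0])
            ijk = grid.unravel(tissue)
            for r in np.flatnonzero(ijk[:, 0] == 0):
                A.rows[r] = [int(r)]
                A.data[r] = [1.0]
                b[r] = c0
            x, _ = pf.solve_sparse(A.tocsr(), b, rtol=1e-12)
            xc = grid.axis_centers(0)
            exact = c0 * np.cosh(lam * (L - xc)) / np.cosh(lam * (L - xc[0]))
            line = np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)],
                            axis=1)
            num = x[index[grid.linear_index(line)]]
            errors.append(np.max(np.abs(num - exact)))
        assert 3.5 <= errors[0] / errors[1] <= 4.5
        assert 3.5 <= errors[1] / errors[2] <= 4.5
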