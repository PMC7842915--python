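import numpy as np
import pytest

import perfusim as pf
from perfusim.analysis import (
    DEPTH_PLANES,
    HYPOXIA_THRESHOLDS,
    coarse_average_map,
    default_rays,
    mean_relative_error_percent,
    profile_deviation,
)
from perfusim.errors import ParameterError

from conftest import solve_cortex_oxygen


@pytest.fixture(scope="module")
def oxygen_solution(cortex, cortex_flow):
    net, bc = cortex
    return solve_cortex_oxygen(net, bc, cortex_flow, n_cells=24)


class TestOxygenAudit:
    def test_closure_from_raw_blocks(self, cortex, cortex_flow, oxygen_solution):
        net, bc = cortex
        fa = pf.flow_mass_audit(net, bc, cortex_flow.f)
        audit = pf.oxygen_mass_audit(oxygen_solution.system, oxygen_solution, fa)
        assert audit.oxygen_inlet == pytest.approx(
            audit.oxygen_outlet + audit.oxygen_transfer, rel=1e-8
        )
        assert audit.oxygen_loss_percent <= 1.5e-8

    def test_zero_permeability_zero_transfer(self, cortex, cortex_flow):
        net, bc = cortex
        params = pf.PhysiologyParams(U=1e-300)
        sol = solve_cortex_oxygen(net, bc, cortex_flow, n_cells=16, params=params)
        audit = pf.oxygen_mass_audit(sol.system, sol)
        assert abs(audit.oxygen_transfer) <= 1e-280


class TestRaytracing:
    def test_default_ray_count_is_25(self, oxygen_solution):
        rays = default_rays(oxygen_solution.system.grid)
        assert len(rays) == 25
        profiles, _ = pf.raytrace_profiles(oxygen_solution)
        assert profiles.shape[0] == 25

    def test_uniform_field_constant_profiles(self, oxygen_solution):
        sol = oxygen_solution
        const = pf.OxygenSolution(
            cv=np.full_like(sol.cv, 4.2),
            ct=np.full_like(sol.ct, 4.2),
            system=sol.system,
        )
        profiles, _ = pf.raytrace_profiles(const, n_samples=40)
        np.testing.assert_allclose(profiles, 4.2, rtol=1e-12)

    def test_missing_ray_flagged_empty(self, oxygen_solution):
        profiles, _ = pf.raytrace_profiles(
            oxygen_solution,
            rays=[((-1000.0, -1000.0, -1000.0), (0.0, 0.0, -1.0))],
        )
        assert np.all(np.isnan(profiles))

    def test_deviation_statistics(self):
        a = np.zeros((3, 10))
        b = np.full((3, 10), 2.0)
        d = profile_deviation(a, b)
        assert d["max"] == pytest.approx(2.0)
        assert d["per_ray_max"].shape == (3,)


class TestHypoxia:
    def test_uniform_fields(self, oxygen_solution):
        sol = oxygen_solution
        high = pf.OxygenSolution(cv=np.full_like(sol.cv, 30.0),
                                 ct=np.full_like(sol.ct, 30.0), system=sol.system)
        low = pf.OxygenSolution(cv=np.zeros_like(sol.cv),
                                ct=np.zeros_like(sol.ct), system=sol.system)
        fr_high = pf.hypoxic_fraction(high)
        fr_low = pf.hypoxic_fraction(low)
        for thr in HYPOXIA_THRESHOLDS:
            assert fr_high[thr]["fraction"] == 0.0
            assert fr_low[thr]["fraction"] == 1.0

    def test_monotone_in_threshold(self, oxygen_solution):
        fr = pf.hypoxic_fraction(oxygen_solution)
        assert fr[5.0]["fraction"] <= fr[10.0]["fraction"] <= fr[15.0]["fraction"]

    def test_components_volumes_consistent(self, oxygen_solution):
        fr = pf.hypoxic_fraction(oxygen_solution, thresholds=[10.0])
        rec = fr[10.0]
        grid = oxygen_solution.system.grid
        labels = oxygen_solution.system.labels
        n_hyp = int(round(rec["fraction"]
                          * (grid.n_cells - labels.n_interior)))
        assert rec["component_volumes_um3"].sum() == pytest.approx(
            n_hyp * grid.cell_volume
        )

    def test_empty_roi_rejected(self, oxygen_solution):
        with pytest.raises(ParameterError):
            pf.hypoxic_fraction(oxygen_solution,
                                roi=((-10.0, -10.0, -10.0), (-1.0, -1.0, -1.0)))


class TestAging:
    def test_identity_scenario(self, cortex):
        net, bc = cortex
        n2, b2 = pf.aging_scenario(net, bc, mode="young")
        assert not n2.occluded.any()
        assert b2.inlet_hematocrit == bc.inlet_hematocrit

    def test_default_perturbations(self, cortex):
        net, bc = cortex
        n2, b2 = pf.aging_scenario(net, bc, seed=4, mode="combined")
        caps = np.flatnonzero(net.vessel_class == "capillary")
        assert n2.occluded.sum() == int(np.floor(0.30 * caps.size))
        assert np.all(n2.diameter[n2.occluded] == 0.0)
        for v in b2.inlet_hematocrit.values():
            assert v == pytest.approx(0.7 * 0.35)

    def test_seeded_occlusion_set_reproducible(self, cortex):
        net, bc = cortex
        a, _ = pf.aging_scenario(net, bc, seed=9, mode="occlusions")
        b, _ = pf.aging_scenario(net, bc, seed=9, mode="occlusions")
        np.testing.assert_array_equal(a.occluded, b.occluded)

    def test_hypoxia_increases_with_age_when_field_is_sensitive(
        self, cortex, cortex_flow
    ):
        """Directional claim with a moderate metabolic rate, where the tissue
        field retains dynamic range around the 10 mmHg threshold."""
        net, bc = cortex
        params = pf.PhysiologyParams(k_met=10.0)
        young = solve_cortex_oxygen(net, bc, cortex_flow, n_cells=16,
                                    params=params)
        fr_young = pf.hypoxic_fraction(young, thresholds=[10.0])[10.0]["fraction"]
        n2, b2 = pf.aging_scenario(net, bc, seed=4, mode="combined")
        flow2 = pf.fixed_point_hemodynamics(n2, b2)
        aged = solve_cortex_oxygen(n2, b2, flow2, n_cells=16, params=params)
        fr_aged = pf.hypoxic_fraction(aged, thresholds=[10.0])[10.0]["fraction"]
        assert fr_aged > fr_young


class TestDepthAndMaps:
    def test_default_depths(self):
        assert DEPTH_PLANES == (120.0, 280.0, 480.0, 680.0, 880.0)

    def test_linear_field_slice_values(self, oxygen_solution):
        sol = oxygen_solution
        grid = sol.system.grid
        zc = grid.axis_centers(2)
        linear = np.broadcast_to(zc, grid.shape).copy()
        fake = pf.OxygenSolution(cv=sol.cv, ct=sol.ct, system=sol.system)
        fake.reconstructed_field = lambda: linear
        maps = pf.depth_plane_map(fake, depths=[120.0, 280.0])
        for depth, (k, plane) in maps.items():
            assert abs(plane[0, 0] - depth) <= grid.spacing / 2

    def test_outside_depth_skipped_with_warning(self, oxygen_solution):
        with pytest.warns(UserWarning, match="outside"):
            maps = pf.depth_plane_map(oxygen_solution, depths=[120.0, 5000.0])
        assert list(maps) == [120.0]

    def test_adjacent_depths_differ_by_one_layer(self, oxygen_solution):
        grid = oxygen_solution.system.grid
        zc = grid.axis_centers(2)
        maps = pf.depth_plane_map(oxygen_solution, depths=[zc[3], zc[4]])
        ks = [k for k, _ in maps.values()]
        assert ks[1] - ks[0] == 1

    def test_coarse_average_blocks(self):
        rng = np.random.default_rng(0)
        dense = rng.uniform(size=(200, 200))
        coarse = coarse_average_map(dense, (20, 20))
        assert coarse.shape == (20, 20)
        assert coarse[3, 7] == pytest.approx(dense[30:40, 70:80].mean())
        # plane mean conserved exactly
        assert coarse.mean() == pytest.approx(dense.mean())

    def test_constant_map_zero_error(self):
        m = np.full((20, 20), 5.0)
        assert mean_relative_error_percent(m, m) == 0.0

    def test_indivisible_shape_warns(self):
        with pytest.warns(UserWarning, match="cropped"):
            coarse_average_map(np.ones((21, 21)), (2, 2))


class TestROI:
    def test_full_domain_identity(self, oxygen_solution):
        grid = oxygen_solution.system.grid
        field = oxygen_solution.reconstructed_field()
        sub_grid, sub = pf.extract_roi(grid, field, (grid.bounds[0], grid.bounds[1]))
        assert sub.shape == field.shape
        np.testing.assert_array_equal(sub, field)

    def test_cell_count_product(self, oxygen_solution):
        grid = oxygen_solution.system.grid
        field = oxygen_solution.reconstructed_field()
        sub_grid, sub = pf.extract_roi(grid, field,
                                       ((50.0, 50.0, 50.0), (250.0, 250.0, 250.0)))
        assert sub.size == np.prod(sub.shape)
        assert sub.shape == sub_grid.shape

    def test_roi_excludes_desaturated_rim(self, oxygen_solution):
        """A low-oxygen rim changes the full-domain tally but not the ROI's."""
        sol = oxygen_solution
        grid = sol.system.grid
        field = sol.reconstructed_field()
        rim = field.copy()
        rim[0, :, :] = 0.0
        rim[-1, :, :] = 0.0
        fake = pf.OxygenSolution(cv=sol.cv, ct=sol.ct, system=sol.system)
        fake.reconstructed_field = lambda: rim
        roi = ((50.0, 50.0, 50.0), (250.0, 250.0, 250.0))
        full_before = pf.hypoxic_fraction(sol, thresholds=[10.0])[10.0]["fraction"]
        full_after = pf.hypoxic_fraction(fake, thresholds=[10.0])[10.0]["fraction"]
        roi_before = pf.hypoxic_fraction(sol, thresholds=[10.0], roi=roi)[10.0]["fraction"]
        roi_after = pf.hypoxic_fraction(fake, thresholds=[10.0], roi=roi)[10.0]["fraction"]
        assert full_after >= full_before
        assert roi_after == roi_before

    def test_network_roi(self, cortex):
        net, _ = cortex
        sub = pf.extract_roi_network(net, ((50.0,) * 3, (250.0,) * 3))
        assert sub.n_segments < net.n_segments
        sub.validate()
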