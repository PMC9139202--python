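"""Wall shear stress extraction and extreme-site detection."""

import numpy as np
import pytest

from aneuchip import (
    AneurysmParams,
    DimensionalScaling,
    SolverConfig,
    compute_wss,
    extract_wall_faces,
    find_extreme_sites,
    make_sidewall_aneurysm,
    make_straight_vessel,
    solve_steady,
    time_average_wss,
)
from aneuchip.errors import UsageError
from aneuchip.solver import FlowSolution
from aneuchip.wss import WSSField

D = 4.0e-3


def _linear_shear_solution(mask, G, reynolds=10.0):
    """Manufactured u = G*y, v = 0 on the mask's grid (nondimensional)."""
    nx, ny = mask.shape
    h = mask.spacing / mask.inlet_width()
    y_face = (np.arange(ny) + 0.5) * h
    u = np.tile(G * y_face, (nx + 1, 1))
    v = np.zeros((nx, ny + 1))
    return FlowSolution(u=u, v=v, p=np.zeros((nx, ny)), time=0.0, h=h,
                        mask=mask, length_scale=mask.inlet_width(),
                        reynolds=reynolds)


class TestExtractWallFaces:
    def test_straight_channel_walls_and_normals(self):
        mask = make_straight_vessel(AneurysmParams(), D / 16,
                                    wall_offset=3 * (D / 16))
        idx, pos, nrm = extract_wall_faces(mask)
        rows = np.unique(idx[:, 1])
        assert len(rows) == 2  # one face row per wall
        assert np.allclose(np.linalg.norm(nrm, axis=1), 1.0, atol=1e-6)
        lower = idx[:, 1] == rows.min()
        assert np.allclose(nrm[lower], [0.0, -1.0])
        assert np.allclose(nrm[~lower], [0.0, 1.0])

    def test_wall_face_count_matches_channel_perimeter(self):
        n = 16
        mask = make_straight_vessel(AneurysmParams(), D / n,
                                    wall_offset=3 * (D / n))
        idx, _, _ = extract_wall_faces(mask)
        # two wall rows of nx faces each (ports are open ends)
        assert len(idx) == 2 * mask.shape[0]

    def test_voxel_sphere_normals_point_radially(self):
        # spherical cavity: fluid inside a solid block
        n = 64
        c = (n - 1) / 2.0
        jj = np.indices((n, n))
        r2 = (jj[0] - c) ** 2 + (jj[1] - c) ** 2
        ind = np.where(r2 < (n / 3) ** 2, 0, 1).astype(np.uint8)
        from aneuchip.geometry import VoxelMask

        mask = VoxelMask(ind, 1e-4, (0.0, 0.0))
        idx, pos, nrm = extract_wall_faces(mask)
        center = np.array([(c + 0.5) * 1e-4] * 2)
        radial = pos - center
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        cosines = np.sum(nrm * radial, axis=1)
        assert cosines.min() >= 0.9

    def test_all_fluid_mask_rejected(self):
        from aneuchip.geometry import VoxelMask

        mask = VoxelMask(np.zeros((8, 8), np.uint8), 1e-4, (0.0, 0.0))
        with pytest.raises(UsageError):
            extract_wall_faces(mask)


class TestComputeWSS:
    def test_manufactured_linear_shear_is_exact(self):
        mask = make_straight_vessel(AneurysmParams(), D / 16,
                                    wall_offset=3 * (D / 16))
        G = 2.5
        sol = _linear_shear_solution(mask, G, reynolds=10.0)
        w = compute_wss(sol)
        # tau = (1/Re) * |du/dy|; the linear field is differenced exactly
        rows = np.unique(w.indices[:, 1])
        lower = w.indices[:, 1] == rows.min()
        y_low = (rows.min() + 0.5) * sol.h
        expect_low = (1 / 10.0) * G * y_low / (0.5 * sol.h)
        assert np.allclose(w.tau[lower], expect_low, rtol=1e-12)

    def test_zero_field_gives_zero_tau(self):
        mask = make_straight_vessel(AneurysmParams(), D / 16)
        sol = _linear_shear_solution(mask, 0.0)
        w = compute_wss(sol)
        assert np.all(w.tau == 0.0)

    def test_poiseuille_wall_stress_matches_6muU_over_H(self, poiseuille_32):
        w = compute_wss(poiseuille_32)
        # nondim: 6 * (1/Re) * U/H with U = H = 1
        expected = 6.0 / 250.0
        assert np.median(w.tau) == pytest.approx(expected, rel=0.03)

    def test_dimensional_scaling_reproduces_chip_formula(self, poiseuille_32):
        scal = DimensionalScaling()
        w = compute_wss(poiseuille_32, scaling=scal)
        # 6 mu U / H for blood in the 4 mm vessel
        mu = scal.rho * scal.nu
        expected = 6.0 * mu * scal.U / scal.D
        assert np.median(w.tau_pa) == pytest.approx(expected, rel=0.03)

    def test_scaling_linearity_of_tau_in_velocity(self):
        mask = make_straight_vessel(AneurysmParams(), D / 16,
                                    wall_offset=3 * (D / 16))
        w1 = compute_wss(_linear_shear_solution(mask, 1.0))
        w3 = compute_wss(_linear_shear_solution(mask, 3.0))
        assert np.allclose(w3.tau, 3.0 * w1.tau)

    def test_wall_tau_error_decreases_under_refinement(self):
        params = AneurysmParams(vessel_length=2 * D)
        errs = []
        for n in (16, 32, 64):
            mask = make_straight_vessel(params, D / n, wall_offset=0.375 * D)
            sol = solve_steady(mask, SolverConfig(reynolds=50.0, steady_tol=1e-7))
            w = compute_wss(sol)
            errs.append(abs(np.median(w.tau) - 6.0 / 50.0) / (6.0 / 50.0))
        assert errs[0] > errs[1] > errs[2]


class TestTimeAverage:
    def _field(self, tau):
        n = len(tau)
        idx = np.column_stack([np.arange(n), np.zeros(n, int)])
        pos = idx.astype(float)
        nrm = np.tile([0.0, 1.0], (n, 1))
        from aneuchip.geometry import VoxelMask

        mask = VoxelMask(np.ones((n, 2), np.uint8), 1.0, (0.0, 0.0))
        return WSSField(idx, pos, nrm, np.asarray(tau, float), mask)

    def test_identical_snapshots_idempotent(self):
        f = self._field([1.0, 2.0, 3.0])
        avg, peak = time_average_wss([f, f, f])
        assert np.allclose(avg.tau, f.tau)
        assert np.allclose(peak.tau, f.tau)
        assert avg.kind == "time_averaged" and peak.kind == "peak"

    def test_mean_and_peak_arithmetic(self):
        f1 = self._field([1.0, 2.0])
        f3 = self._field([3.0, 6.0])
        avg, peak = time_average_wss([f1, f3])
        assert np.allclose(avg.tau, [2.0, 4.0])
        assert np.allclose(peak.tau, [3.0, 6.0])

    def test_mismatched_face_sets_rejected(self):
        with pytest.raises(UsageError):
            time_average_wss([self._field([1.0]), self._field([1.0, 2.0])])

    def test_single_snapshot_rejected(self):
        with pytest.raises(UsageError):
            time_average_wss([self._field([1.0])])


class TestExtremeSites:
    def _line_field(self, tau):
        n = len(tau)
        idx = np.column_stack([np.arange(n), np.full(n, 1, int)])
        pos = idx.astype(float) * 1e-4
        nrm = np.tile([0.0, 1.0], (n, 1))
        from aneuchip.geometry import VoxelMask

        ind = np.ones((n, 3), np.uint8)
        ind[:, 1] = 0
        mask = VoxelMask(ind, 1e-4, (0.0, 0.0))
        return WSSField(idx, pos, nrm, np.asarray(tau, float), mask)

    def test_brute_force_percentiles_on_line(self):
        tau = np.arange(1.0, 101.0)
        sites = find_extreme_sites(self._line_field(tau), 5, 95, min_region_faces=1)
        low = sites.low_sites[0]
        high = sites.high_sites[0]
        assert sorted(low.member_indices[:, 0]) == [0, 1, 2, 3, 4]      # tau 1..5
        assert sorted(high.member_indices[:, 0]) == [95, 96, 97, 98, 99]  # tau 96..100
        assert low.tau_median == 3.0
        assert high.tau_median == 98.0

    def test_constant_field_yields_no_sites(self):
        sites = find_extreme_sites(self._line_field(np.full(50, 2.0)), 5, 95, 1)
        assert sites.low_sites == [] and sites.high_sites == []

    def test_representatives_bracket_field_median(self, aneurysm_solution):
        w = compute_wss(aneurysm_solution)
        sites = find_extreme_sites(w)
        assert sites.low_sites and sites.high_sites
        med = np.median(w.tau)
        assert sites.low_sites[0].tau_median < med < sites.high_sites[0].tau_median

    def test_min_region_size_filters_small_regions(self):
        tau = np.full(100, 1.0)
        tau[10] = 100.0  # single-face spike
        sites = find_extreme_sites(self._line_field(tau), 5, 95, min_region_faces=3)
        assert sites.high_sites == []

    def test_invalid_percentiles_rejected(self):
        f = self._line_field(np.arange(10.0))
        with pytest.raises(UsageError):
            find_extreme_sites(f, 95, 5)

    def test_aneurysm_high_site_at_downstream_neck_rim(self, aneurysm_solution):
        """The flow impinges on the downstream sac-vessel junction: the
        top-ranked high-shear site must sit within two neck widths of the
        downstream rim, and the top low-shear site on the sac wall away
        from the neck."""
        w = compute_wss(aneurysm_solution, scaling=DimensionalScaling())
        sites = find_extreme_sites(w)
        neck = 1.28e-3
        rim_down = np.array([8e-3 + neck / 2, 0.15 * D + D])
        high = sites.high_sites[0]
        assert np.linalg.norm(high.centroid - rim_down) < 2 * neck
        low = sites.low_sites[0]
        sac_center = np.array([8e-3, 0.15 * D + D + np.sqrt(1.6e-3**2 - (neck / 2) ** 2)])
        r_low = np.linalg.norm(low.centroid - sac_center)
        assert abs(r_low - 1.6e-3) < 0.5e-3        # on the sac wall
        assert low.centroid[1] > rim_down[1] + neck  # away from the neck plane
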