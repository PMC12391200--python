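"""Tests for the disc mesh, element post-processing and the u-p solver."""

import numpy as np
import pytest

from discbiphasic import BiphasicMaterial
from discbiphasic.disc_fem import (DiscGeometry, build_cylinder_mesh,
                                   build_disc_mesh, fluid_flux, peak_table,
                                   solve_biphasic, unconfined_reaction_force,
                                   von_mises)
from discbiphasic.disc_fem.mesh import REGION_CODES, DiscMesh, _boundary_sets
from discbiphasic.disc_fem.postprocess import lagrange_strain
from discbiphasic.disc_fem.solver import CompressionProtocol
from discbiphasic.disc_fem.unconfined import (characteristic_roots,
                                              unconfined_step_modulus)
from discbiphasic.errors import DomainError

from conftest import rel_err


class TestMesh:
    def test_positive_jacobians(self, disc_mesh_res8):
        assert np.all(disc_mesh_res8.element_volumes() > 0)

    def test_region_partition(self, disc_mesh_res8):
        labels = disc_mesh_res8.region_labels
        assert set(np.unique(labels)) == {0, 1, 2}
        vols = disc_mesh_res8.element_volumes()
        total = vols.sum()
        by_region = [vols[labels == c].sum() for c in (0, 1, 2)]
        assert sum(by_region) == pytest.approx(total, rel=1e-12)

    def test_np_area_fraction(self, disc_mesh_res8):
        vols = disc_mesh_res8.element_volumes()
        core = disc_mesh_res8.region_labels != REGION_CODES["CEP"]
        np_sel = disc_mesh_res8.region_labels == REGION_CODES["NP"]
        frac = vols[np_sel].sum() / vols[core].sum()
        assert abs(frac - 0.4) < 0.1  # grid-granularity tolerance

    def test_volume_convergence(self):
        geom = DiscGeometry()
        v8 = build_disc_mesh(geom, 8).element_volumes().sum()
        v16 = build_disc_mesh(geom, 16).element_volumes().sum()
        assert rel_err(v8, v16) < 0.01

    def test_cep_layers_span_thickness(self, disc_mesh_res8):
        mesh = disc_mesh_res8
        z = mesh.nodes[mesh.elements].mean(axis=1)[:, 2]
        cep = mesh.region_labels == REGION_CODES["CEP"]
        assert z[cep].min() < 0.9e-3
        assert z[cep].max() > (6.0 - 0.9) * 1e-3

    def test_boundary_sets(self, disc_mesh_res8):
        s = disc_mesh_res8.boundary_sets
        for name in ("symmetry", "top", "bottom", "drained", "lateral"):
            assert len(s[name]) > 0
        # top/bottom are drained (exposed endplate surfaces)
        assert set(s["top"]) <= set(s["drained"])
        assert set(s["bottom"]) <= set(s["drained"])
        assert np.all(np.abs(disc_mesh_res8.nodes[s["symmetry"], 1]) < 1e-12)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(DomainError):
            DiscGeometry(cep_thickness=3.0)  # 2*cep >= height
        with pytest.raises(DomainError):
            build_disc_mesh(DiscGeometry(), resolution=2)


class TestVonMises:
    def test_hydrostatic(self):
        assert von_mises(2.5 * np.eye(3)) == pytest.approx(0.0)

    def test_uniaxial(self):
        s = np.zeros((3, 3))
        s[2, 2] = -3.7
        assert von_mises(s) == pytest.approx(3.7)

    def test_eigenvalue_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=(3, 3))
            s = a + a.T
            lam = np.linalg.eigvalsh(s)
            oracle = np.sqrt(0.5 * ((lam[0] - lam[1]) ** 2
                                    + (lam[1] - lam[2]) ** 2
                                    + (lam[2] - lam[0]) ** 2))
            assert abs(von_mises(s) - oracle) < 1e-12 * max(oracle, 1.0)


class TestFluidFlux:
    k = {"AF": 1e-15}

    def test_uniform_pressure(self):
        mesh = build_cylinder_mesh(5.0, 6.0, n_r=4, n_z=2)
        flux = fluid_flux(mesh, self.k, np.full(mesh.n_nodes, 1e4))
        assert np.max(np.abs(flux)) < 1e-20

    def test_linear_pressure_drop(self):
        mesh = build_cylinder_mesh(5.0, 6.0, n_r=4, n_z=2)
        g = 2.0e6  # Pa/m along x
        flux = fluid_flux(mesh, self.k, g * mesh.nodes[:, 0])
        assert np.allclose(flux[:, 0], -1e-15 * g, rtol=1e-10)
        assert np.max(np.abs(flux[:, 1:])) < 1e-12 * 1e-15 * g

    def test_manufactured_quadratic(self):
        # mean flux error for p = y^2 converges at ~2nd order (boundary
        # elements are distorted by the curved rim, so the max-norm rate
        # degrades; the mean captures the interior superconvergence)
        errs = []
        for n_r in (4, 8):
            mesh = build_cylinder_mesh(5.0, 6.0, n_r=n_r, n_z=2)
            p = mesh.nodes[:, 1] ** 2 * 1e9
            flux = fluid_flux(mesh, self.k, p)
            yc = mesh.nodes[mesh.elements].mean(axis=1)[:, 1]
            exact = -1e-15 * 2e9 * yc
            errs.append(np.mean(np.abs(flux[:, 1] - exact)))
        assert errs[1] < 0.4 * errs[0]


class TestUnconfinedSeries:
    mat = BiphasicMaterial(H_A=0.5e6, k=1e-14, nu=0.2)

    def test_characteristic_roots(self):
        roots = characteristic_roots(0.2, 10)
        beta = 0.8 / 0.6
        from scipy.special import j0, j1
        assert np.all(np.abs(j1(roots) - beta * roots * j0(roots)) < 1e-10)
        assert np.all(np.diff(roots) > 0)

    def test_limits(self):
        mu = self.mat.shear_modulus
        m0 = unconfined_step_modulus(self.mat, 1e-12, n_roots=200)
        assert rel_err(m0, 3 * mu) < 1e-3  # undrained isochoric limit
        minf = unconfined_step_modulus(self.mat, 50.0)
        assert rel_err(minf, self.mat.E) < 1e-12  # drained limit

    def test_monotone_relaxation(self):
        T = np.geomspace(1e-4, 20, 50)
        vals = unconfined_step_modulus(self.mat, T)
        assert np.all(np.diff(vals) <= 1e-9 * vals[0])


class TestSolver:
    mat = BiphasicMaterial(H_A=0.5e6, k=1e-14, nu=0.2)

    def test_zero_strain_zero_fields(self):
        mesh = build_cylinder_mesh(5.0, 6.0, n_r=4, n_z=2)
        proto = CompressionProtocol(axial_strain=0.0, ramp_duration=100.0,
                                    hold_until=200.0, n_hold_steps=4)
        res = solve_biphasic(mesh, {"AF": self.mat}, proto, swelling=False)
        assert np.max(np.abs(res.displacement)) < 1e-15
        assert np.max(np.abs(res.pressure)) < 1e-9
        assert np.max(np.abs(res.reaction_force)) < 1e-12

    def test_cylinder_matches_series(self):
        mesh = build_cylinder_mesh(5.0, 6.0, n_r=8, n_z=2)
        proto = CompressionProtocol(axial_strain=0.10, ramp_duration=10_000.0,
                                    hold_until=40_000.0, n_hold_steps=10)
        res = solve_biphasic(mesh, {"AF": self.mat}, proto, swelling=False,
                             drained_set="lateral")
        F_ana = unconfined_reaction_force(self.mat, 5e-3, 0.10, 10_000.0,
                                          res.times[1:]) / 2.0  # half model
        rel = np.abs(res.reaction_force[1:] / F_ana - 1.0)
        assert rel.max() < 0.03

    def test_drained_pressure_zero(self, disc_biphasic_result):
        res = disc_biphasic_result
        drained = res.mesh.boundary_sets["drained"]
        pmax = np.abs(res.pressure).max()
        assert np.abs(res.pressure[:, drained]).max() < 1e-9 * pmax

    def test_fluid_balance(self):
        # net drained outflow equals the mesh volume change step by step
        from discbiphasic.disc_fem.solver import _System
        from discbiphasic.donnan_swelling import IonEnvironment
        mesh = build_cylinder_mesh(5.0, 6.0, n_r=6, n_z=2)
        proto = CompressionProtocol(axial_strain=0.02, ramp_duration=5000.0,
                                    hold_until=10_000.0, n_hold_steps=6)
        res = solve_biphasic(mesh, {"AF": self.mat}, proto, swelling=False)
        sysm = _System(mesh, {"AF": self.mat}, IonEnvironment())
        drained = mesh.boundary_sets["drained"]
        for i in range(1, len(res.times)):
            dt = res.times[i] - res.times[i - 1]
            du = (res.displacement[i] - res.displacement[i - 1]).ravel()
            r_p = sysm.G.T @ du + dt * (sysm.H @ res.pressure[i])
            dV = r_p.sum()                 # total dilatation change
            outflow = r_p[drained].sum()   # exits via constrained nodes
            scale = max(abs(dV), 1e-30)
            assert abs(dV - outflow) < 0.01 * scale

    def test_identical_materials_no_region_effect(self, region_materials):
        # same material everywhere: near-equilibrium peaks agree by region
        mesh = build_disc_mesh(DiscGeometry(), resolution=6)
        mats = {r: self.mat for r in ("NP", "AF", "CEP")}
        proto = CompressionProtocol(axial_strain=0.05, ramp_duration=5000.0,
                                    hold_until=100_000.0, n_hold_steps=10)
        res = solve_biphasic(mesh, mats, proto, swelling=False)
        pt = peak_table(res, {"eq": float(res.times[-1])})
        vm = pt.set_index("region")["von_mises_MPa"]
        assert vm.max() / vm.min() < 1.10

    def test_mirror_symmetry_invariance(self, region_materials):
        proto = CompressionProtocol(axial_strain=0.10, ramp_duration=10_000.0,
                                    hold_until=10_000.0)
        mesh = build_disc_mesh(DiscGeometry(), resolution=4)
        res = solve_biphasic(mesh, region_materials, proto, swelling=False)
        pt = peak_table(res, {"ramp": 10_000.0}).set_index("region")

        nodes_m = mesh.nodes.copy()
        nodes_m[:, 1] *= -1.0
        elems_m = mesh.elements[:, [3, 2, 1, 0, 7, 6, 5, 4]]
        mesh_m = DiscMesh(nodes=nodes_m, elements=elems_m,
                          region_labels=mesh.region_labels.copy(),
                          boundary_sets=_boundary_sets(nodes_m, elems_m))
        res_m = solve_biphasic(mesh_m, region_materials, proto,
                               swelling=False)
        pt_m = peak_table(res_m, {"ramp": 10_000.0}).set_index("region")
        # different node ordering changes LU pivoting, so agreement is
        # to solver roundoff, not bitwise
        for col in ("von_mises_MPa", "pressure_kPa", "flux_mm_s"):
            assert np.allclose(pt[col], pt_m[col], rtol=1e-6)

    def test_missing_material_raises(self):
        mesh = build_disc_mesh(DiscGeometry(), resolution=4)
        with pytest.raises(DomainError):
            solve_biphasic(mesh, {"AF": self.mat},
                           CompressionProtocol(hold_until=10_000.0))


class TestDiscRuns:
    def test_cep_peak_exceeds_np(self, disc_biphasic_result):
        pt = peak_table(disc_biphasic_result).set_index(
            ["time_label", "region"])
        assert pt.loc[("end_of_ramp", "CEP"), "von_mises_MPa"] > \
            pt.loc[("end_of_ramp", "NP"), "von_mises_MPa"]

    def test_pressure_collapse_at_equilibrium(self, disc_biphasic_result):
        res = disc_biphasic_result
        i_ramp = int(np.argmin(np.abs(res.times - res.ramp_end)))
        ratio = np.abs(res.pressure[i_ramp]).max() / \
            np.abs(res.pressure[-1]).max()
        assert ratio >= 1e4

    def test_swelling_amplifies_stress(self, disc_biphasic_result,
                                       disc_swelling_result):
        pt = peak_table(disc_biphasic_result)
        pt_sw = peak_table(disc_swelling_result)
        m = pt.merge(pt_sw, on=["time_label", "region"],
                     suffixes=("", "_sw"))
        assert (m["von_mises_MPa_sw"] > m["von_mises_MPa"]).all()

    def test_oscillation_metric_low(self, disc_biphasic_result):
        assert disc_biphasic_result.oscillation_metric < 0.2

    @pytest.mark.slow
    def test_mesh_refinement_stability(self, region_materials):
        proto = CompressionProtocol(axial_strain=0.10, ramp_duration=10_000.0,
                                    hold_until=10_000.0)
        peaks = {}
        for resl in (8, 12):
            mesh = build_disc_mesh(DiscGeometry(), resolution=resl)
            res = solve_biphasic(mesh, region_materials, proto,
                                 swelling=False)
            pt = peak_table(res, {"ramp": 10_000.0}).set_index("region")
            peaks[resl] = pt["von_mises_MPa"]
        for region in ("NP", "AF", "CEP"):
            assert rel_err(peaks[8][region], peaks[12][region]) < 0.05
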