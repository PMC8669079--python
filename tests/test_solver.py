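"""Discrete operators, unit conversion, monodomain/bidomain stepping."""

import numpy as np
import pytest
import scipy.sparse as sp

from isthmus import geometry as G
from isthmus import ionic as I
from isthmus import solver as S
from isthmus import analysis as A
from isthmus import synthetic as SY


class TestHarmonicMean:
    def test_default_longitudinal_value(self):
        sl, st = S.harmonic_mean_tensor(S.ConductivitySet())
        assert sl == pytest.approx(0.174 * 0.625 / (0.174 + 0.625), rel=1e-12)
        assert sl == pytest.approx(0.1361, abs=5e-5)

    def test_default_transverse_value(self):
        _, st = S.harmonic_mean_tensor(S.ConductivitySet())
        assert st == pytest.approx(0.019 * 0.236 / (0.019 + 0.236), rel=1e-12)
        assert st == pytest.approx(0.01758, abs=5e-6)

    def test_equal_phases_halve(self):
        c = S.ConductivitySet(
            sigma_il=0.3, sigma_el=0.3, sigma_it=0.1, sigma_et=0.1
        )
        sl, st = S.harmonic_mean_tensor(c)
        assert sl == pytest.approx(0.15) and st == pytest.approx(0.05)

    def test_unit_conversion_s_per_m_to_ms_per_cm(self):
        assert 1.0 * S.S_PER_M_TO_MS_PER_CM == 10.0  # 1 S/m == 10 mS/cm


class TestAssembly:
    def test_axis_aligned_fibres_give_five_point_stencil(self, healthy_sheet):
        ops = S.assemble(healthy_sheet)
        L = ops.L_mono.tocsr()
        dx = healthy_sheet.spacing
        sl, st = S.harmonic_mean_tensor(S.ConductivitySet())
        gl = sl * 10.0 / dx**2
        gt = st * 10.0 / dx**2
        # interior node: 4 off-diagonal entries, +x/-x weight sigma_l, +y/-y
        # weight sigma_t, diagonal minus the sum
        n = healthy_sheet.ny
        i = healthy_sheet.nx // 2 * n + n // 2
        loc = ops.to_local("active", np.array([i]))[0]
        row = L.getrow(loc).toarray().ravel()
        off = row[row != row[loc]]
        assert len(row.nonzero()[0]) == 5
        vals = sorted(row[j] for j in row.nonzero()[0] if j != loc)
        assert vals == pytest.approx(sorted([gl, gl, gt, gt]), rel=1e-12)
        assert row[loc] == pytest.approx(-2 * gl - 2 * gt, rel=1e-12)

    def test_rotating_fibres_90_degrees_swaps_axes(self):
        a = G.build_slab_geometry((1.0, 1.0), 0.05, None, (0.0, 0.0),
                                  G.FiberRule(angle=0.0))
        b = G.build_slab_geometry((1.0, 1.0), 0.05, None, (0.0, 0.0),
                                  G.FiberRule(angle=np.pi / 2))
        La = S.assemble(a).L_mono
        Lb = S.assemble(b).L_mono
        n = a.ny
        i = (a.nx // 2) * n + n // 2
        loc = S.assemble(a).to_local("active", np.array([i]))[0]
        ra = La.getrow(loc).toarray().ravel()
        rb = Lb.getrow(loc).toarray().ravel()
        # +x neighbour weight under 0 deg equals +y neighbour weight under 90
        assert ra[loc + n] == pytest.approx(rb[loc + 1], rel=1e-9)
        assert ra[loc + 1] == pytest.approx(rb[loc + n], rel=1e-9)

    def test_all_bath_grid_has_empty_intracellular_operator(self):
        grid = G.build_slab_geometry((0.5, 0.1), 0.05, None, (0.5, 0.5))
        lab = grid.labels.copy()
        lab[:] = G.Label.BATH
        grid.labels = lab
        grid.fiber_angle[:] = np.nan
        ops = S.assemble(grid)
        assert ops.L_i.shape == (0, 0)
        assert ops.L_e_ext.shape[0] == grid.nx * grid.ny

    def test_operators_symmetric_with_zero_row_sums(self, small_infarct_grid):
        ops = S.assemble(small_infarct_grid)
        for L in (ops.L_mono, ops.L_i, ops.L_ie):
            assert abs(L - L.T).max() < 1e-10
            assert np.abs(np.asarray(L.sum(axis=1))).max() < 1e-8

    def test_region_factor_scales_isthmus_conductivity(self, small_infarct_grid):
        base = S.assemble(small_infarct_grid)
        slowed = S.assemble(small_infarct_grid, region_factors={"CI": 0.5})
        ci_local = base.to_local("active", small_infarct_grid.regions["CI"])
        d_base = base.L_mono.diagonal()[ci_local]
        d_slow = slowed.L_mono.diagonal()[ci_local]
        # interior channel nodes see exactly the 0.5 factor
        interior = np.abs(d_slow / d_base - 0.5) < 1e-6
        assert interior.mean() > 0.5


class TestMonodomainStepping:
    def test_uniform_resting_state_is_stationary(self, healthy_sheet):
        ops = S.assemble(healthy_sheet)
        m = I.ReducedModel()
        models = S.ModelMap.uniform(m, len(ops.active_nodes))
        st0 = ops.initial_state(models)
        st = st0.copy()
        for _ in range(20):
            st = S.step_monodomain(st, ops, models, 0.1)
        np.testing.assert_allclose(st.vm, st0.vm, atol=1e-9)

    def test_dt_cap_enforced(self, healthy_sheet):
        ops = S.assemble(healthy_sheet)
        models = S.ModelMap.uniform(I.ReducedModel(), len(ops.active_nodes))
        st = ops.initial_state(models)
        with pytest.raises(ValueError, match="dt"):
            S.step_monodomain(st, ops, models, 0.2)

    def test_border_zone_conductivity_slows_planar_wave(self):
        def cv(bz):
            grid = G.build_slab_geometry((2.0, 0.15), 0.025, None, (0.0, 0.0))
            if bz:
                lab = grid.labels.copy()
                lab[grid.active_mask] = G.Label.BZ
                grid.labels = lab
            ops = S.assemble(grid)
            models = S.ModelMap.uniform(I.ReducedModel(), len(ops.active_nodes))
            return A.measure_cv(grid, ops, models, direction="x")

        cv_h, cv_bz = cv(False), cv(True)
        assert cv_bz < cv_h
        # diffusive scaling: halved conductivity -> CV / sqrt(2)
        assert cv_bz == pytest.approx(cv_h / np.sqrt(2), rel=0.08)

    def test_doubled_conductivities_scale_cv_by_sqrt2(self):
        def cv(mult):
            grid = G.build_slab_geometry((2.4, 0.15), 0.025, None, (0.0, 0.0))
            c = S.ConductivitySet()
            from dataclasses import replace

            c = replace(
                c,
                sigma_il=c.sigma_il * mult,
                sigma_el=c.sigma_el * mult,
                sigma_it=c.sigma_it * mult,
                sigma_et=c.sigma_et * mult,
            )
            ops = S.assemble(grid, c)
            models = S.ModelMap.uniform(I.ReducedModel(), len(ops.active_nodes))
            return A.measure_cv(grid, ops, models, direction="x")

        assert cv(2.0) == pytest.approx(cv(1.0) * np.sqrt(2), rel=0.05)

    def test_planar_cv_converged_under_mesh_refinement(self):
        # halving the pitch changes planar CV by < 3% (fixed reaction dt)
        cvs = []
        for dx in (0.025, 0.0125):
            grid = G.build_slab_geometry((2.0, 0.1), dx, None, (0.0, 0.0))
            ops = S.assemble(grid)
            models = S.ModelMap.uniform(I.ReducedModel(), len(ops.active_nodes))
            cvs.append(A.measure_cv(grid, ops, models, "x", dt=0.05))
        assert abs(cvs[1] - cvs[0]) / cvs[0] < 0.03

    def test_transverse_cv_below_longitudinal(self):
        gx = G.build_slab_geometry((2.0, 0.15), 0.025, None, (0.0, 0.0))
        gy = G.build_slab_geometry((0.15, 2.0), 0.025, None, (0.0, 0.0))
        mx = S.ModelMap.uniform(I.ReducedModel(), int(gx.active_mask.sum()))
        my = S.ModelMap.uniform(I.ReducedModel(), int(gy.active_mask.sum()))
        cv_l = A.measure_cv(gx, S.assemble(gx), mx, "x")
        cv_t = A.measure_cv(gy, S.assemble(gy), my, "y", t_max=400.0)
        assert cv_t < cv_l


class TestPassiveCable:
    def test_steady_state_decay_matches_cable_theory(self):
        spec = SY.FixtureSpec(seed=0, family="passive_cable")
        grid, cset, g_m, lam, profile = SY.make_passive_cable(spec)
        ops = S.assemble(grid, cset)
        model = I.PassiveModel(g_m=g_m)
        models = S.ModelMap.uniform(model, len(ops.active_nodes))
        st = ops.initial_state(models)
        # clamp the x=0 line 20 mV above rest, step to steady state
        xcols = grid.coords(ops.active_nodes)[:, 0]
        clamp = np.flatnonzero(xcols < grid.spacing / 2)
        loc = ops.active_in_tissue[clamp]
        # fine dt: first-order splitting biases the effective membrane
        # conductance by ~dt*g_m/2, which would alias into lambda
        for _ in range(6000):
            st = S.step_monodomain(st, ops, models, 0.02)
            st.vm[loc] = model.v_rest + 20.0
        x = grid.coords(ops.tissue_nodes)[:, 0]
        v = st.vm - model.v_rest
        # fit exp decay over 1..5 lambda
        sel = (x > lam) & (x < 5 * lam) & (v > 1e-6)
        slope = np.polyfit(x[sel], np.log(v[sel]), 1)[0]
        lam_fit = -1.0 / slope
        assert lam_fit == pytest.approx(lam, rel=0.02)

    def test_analytic_lambda_value_and_scaling(self):
        lam1 = SY.cable_lambda(g_m=1.0)
        lam2 = SY.cable_lambda(g_m=2.0)
        sml = S.harmonic_mean_tensor(S.ConductivitySet())[0] * 10.0
        assert lam1 == pytest.approx(np.sqrt(sml / 1400.0), rel=1e-12)
        assert lam1 / lam2 == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_short_cable_rejected(self):
        with pytest.raises(ValueError, match="10"):
            SY.make_passive_cable(
                SY.FixtureSpec(params={"length_lambdas": 5.0})
            )


class TestBidomain:
    def test_zero_drive_quiescent_gauge(self, healthy_sheet):
        ops = S.assemble(healthy_sheet)
        models = S.ModelMap.uniform(I.ReducedModel(), len(ops.active_nodes))
        st = ops.initial_state(models)
        st = S.step_bidomain(st, ops, models, 0.05)
        assert np.abs(st.phi_e).max() < 1e-8
        assert np.abs(st.vm - models.v_rest).max() < 1e-8

    def test_phi_linear_in_applied_voltage_on_passive_tissue(
        self, small_infarct_grid
    ):
        grid = small_infarct_grid
        es = G.place_transmural_pair(grid, clearance=0.6)
        ops = S.assemble(grid)
        models = S.ModelMap.uniform(
            I.PassiveModel(g_m=0.5, v_rest=-80.0), len(ops.active_nodes)
        )
        st = ops.initial_state(models)
        phis = []
        for v in (10.0, 20.0):
            phi = S.solve_extracellular(
                ops, st,
                dirichlet=[(es.applied_nodes, v * 1e3), (es.ground_nodes, 0.0)],
            )
            phis.append(phi)
        np.testing.assert_allclose(phis[1], 2.0 * phis[0], atol=1e-6)

    def test_field_energy_quadratic_and_split(self, small_infarct_grid):
        grid = small_infarct_grid
        es = G.place_transmural_pair(grid, clearance=0.6)
        ops = S.assemble(grid)
        models = S.ModelMap.uniform(I.PassiveModel(), len(ops.active_nodes))
        st = ops.initial_state(models)

        def energy(v):
            phi = S.solve_extracellular(
                ops, st,
                dirichlet=[(es.applied_nodes, v * 1e3), (es.ground_nodes, 0.0)],
            )
            return A.field_energy(phi, ops, duration=5.0)

        e1, e2 = energy(10.0), energy(20.0)
        assert e2["total_J"] == pytest.approx(4 * e1["total_J"], rel=1e-6)
        assert 0 < e1["tissue_J"] < e1["total_J"]
        assert e1["tissue_fraction"] == pytest.approx(
            e1["tissue_J"] / e1["total_J"]
        )

    def test_zero_voltage_shock_leaves_trajectory_unchanged(self, healthy_sheet):
        grid = healthy_sheet
        # add bath so electrodes exist
        grid = G.build_slab_geometry((2.0, 1.0), 0.05,
                                     G.ScarSpec(band_thickness=0.5,
                                                isthmus_width=0.2,
                                                bz_rim=0.05,
                                                islet_width=0.0,
                                                islet_margin=0.0),
                                     (0.8, 0.8))
        es = G.place_transmural_pair(grid, cube_edge=0.2, clearance=0.5)
        ops = S.assemble(grid)
        models = S.ModelMap.uniform(I.ReducedModel(), len(ops.active_nodes))
        st = ops.initial_state(models)
        # perturb: a propagating wave
        st.vm[ops.active_in_tissue[:50]] = 0.0
        ref = st.copy()
        for _ in range(40):
            ref = S.step_bidomain(ref, ops, models, 0.025)
        shocked, _ = S.apply_shock(
            st.copy(), ops, S.ShockSpec(es, voltage=0.0, duration=1.0), models
        )
        # grounding remote electrode faces at 0 V must not perturb the wave
        assert np.abs(shocked.vm - ref.vm).max() < 0.1

    def test_overlapping_dirichlet_sets_rejected(self, small_infarct_grid):
        grid = small_infarct_grid
        es = G.place_transmural_pair(grid, clearance=0.6)
        ops = S.assemble(grid)
        models = S.ModelMap.uniform(I.ReducedModel(), len(ops.active_nodes))
        st = ops.initial_state(models)
        bad = G.ElectrodeSet(
            [(es.applied_nodes, G.APPLIED), (es.applied_nodes, G.GROUND)],
            "transmural_pair",
            meta={"n_cubes": 2},
        )
        with pytest.raises(ValueError, match="disjoint"):
            S.apply_shock(st, ops, S.ShockSpec(bad, 10.0), models)
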