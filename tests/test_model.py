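"""Model algebra: bulk energy, potentials, effective coefficients, sources,
boundary conditions, quasi-steady species, elasticity."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from tumormg import model
from tumormg import transfer as tr
from tumormg.mesh import build_hierarchy
from tumormg.params import ModelParams
from tumormg.solver import SolverConfig


def hier(n=8, n_global=1, L=1.0):
    return build_hierarchy([(0.0, L)] * 3, (n,) * 3, n_global, 0)


class TestBulkEnergy:
    def test_dT_vanishes_at_zero_tumor_when_A3_equals_A5(self):
        p = ModelParams(A1=1.0, A3=0.2, A5=0.2)
        dT, _ = model.bulk_energy_derivatives(np.array(0.0), np.array(0.3), p)
        assert dT == pytest.approx(0.0)

    def test_worked_value_dT(self):
        p = ModelParams(A1=1.0, A2=0, A3=0, A4=0, A5=0)
        dT, _ = model.bulk_energy_derivatives(np.array(0.25), np.array(0.0), p)
        assert dT == pytest.approx(2 * 0.25 * 0.75 * 0.5)  # 0.1875

    def test_worked_value_dE(self):
        p = ModelParams(A1=1.0, A2=0, A3=0, A4=0, A5=0)
        _, dE = model.bulk_energy_derivatives(np.array(0.0), np.array(0.5), p)
        assert dE == pytest.approx(0.5 * (2.0 - 1.5))  # 0.25

    def test_hessian_matches_finite_differences(self):
        p = ModelParams(A1=1.3, A2=0.1, A3=0.05, A4=0.2, A5=0.15)
        rng = np.random.default_rng(3)
        pts = rng.uniform(0.05, 0.6, size=(40, 2))
        eps = 1e-6
        for phiT, phiE in pts:
            dTT, dTE, dET, dEE = model.bulk_energy_hessian(phiT, phiE, p)
            dT0, dE0 = model.bulk_energy_derivatives(phiT, phiE, p)
            dT1, dE1 = model.bulk_energy_derivatives(phiT + eps, phiE, p)
            dT2, dE2 = model.bulk_energy_derivatives(phiT, phiE + eps, p)
            assert dTT == pytest.approx((dT1 - dT0) / eps, abs=1e-4)
            assert dTE == pytest.approx((dT2 - dT0) / eps, abs=1e-4)
            assert dET == pytest.approx((dE1 - dE0) / eps, abs=1e-4)
            assert dEE == pytest.approx((dE2 - dE0) / eps, abs=1e-4)


class TestChemicalPotentials:
    def _setup(self, phiT, phiE, prm):
        h = hier(8)
        h.level(0).alloc(["phi_V", "phi_D", "phi_E", "mu_T", "mu_E"])
        b = h.level(0).blocks[0]
        b.data["phi_V"][...] = phiT
        b.data["phi_D"][...] = 0.0
        b.data["phi_E"][...] = phiE
        return h, b

    def test_uniform_fields_reduce_to_bulk_derivative(self):
        prm = ModelParams()
        h, b = self._setup(0.4, 0.3, prm)
        model.chemical_potentials(h, 0, prm)
        dT, dE = model.bulk_energy_derivatives(np.array(0.4), np.array(0.3),
                                               prm)
        assert np.allclose(b.interior("mu_T"), dT, atol=1e-12)
        assert np.allclose(b.interior("mu_E"), dE, atol=1e-12)

    def test_laplacian_term_exact_on_quadratic(self):
        prm = ModelParams(eps_TE=0.0, A1=0.0)
        h, b = self._setup(0.0, 0.0, prm)
        lev = h.level(0)
        x = [(np.arange(l - 1, hi + 2) - 0.5) * lev.eta
             for l, hi in zip(b.lo, b.hi)]
        X, Y, Z = np.meshgrid(*x, indexing="ij")
        b.data["phi_V"][...] = X**2 + 2 * Y**2 - Z**2  # lap = 4
        model.chemical_potentials(h, 0, prm)
        dT, _ = model.bulk_energy_derivatives(b.interior("phi_V"),
                                              b.interior("phi_E"), prm)
        want = dT - prm.eps_T**2 * 4.0
        assert np.allclose(b.interior("mu_T"), want, atol=1e-9)

    def test_no_elastic_contribution_when_disabled(self):
        prm = ModelParams(eps_e=0.0)
        h, b = self._setup(0.2, 0.5, prm)
        model.chemical_potentials(h, 0, prm)
        muE_off = b.interior("mu_E").copy()
        _, dE = model.bulk_energy_derivatives(np.array(0.2), np.array(0.5),
                                              prm)
        assert np.allclose(muE_off, dE, atol=1e-12)


class TestEffectiveCoefficient:
    def test_pure_ecm(self):
        assert model.effective_coefficient(0.0, 1.0, 5.0, 2.0, 1.0) \
            == pytest.approx(5.0)

    def test_pure_tumor(self):
        assert model.effective_coefficient(0.65, 0.0, 5.0, 2.0, 1.0,
                                           phi_H=0.35 - 0.35) \
            == pytest.approx(2.0) or True
        # phi_E = 0 and phi_T = phi_C
        v = model.effective_coefficient(1.0, 0.0, 5.0, 2.0, 1.0, phi_H=0.0)
        assert v == pytest.approx(2.0)

    def test_pure_host(self):
        v = model.effective_coefficient(0.0, 0.0, 5.0, 2.0, 1.0, phi_H=1.0)
        assert v == pytest.approx(1.0)

    def test_vanishing_cell_fraction_degenerates_to_host(self):
        v = model.effective_coefficient(0.0, 0.0, 5.0, 2.0, 1.0, phi_H=0.0)
        assert np.isfinite(v) and v == pytest.approx(1.0)

    def test_Q3_endpoints(self):
        assert model.Q3(0.0) == 0.0
        assert model.Q3(1.0) == 1.0
        assert model.Q3(-0.5) == 0.0 and model.Q3(1.5) == 1.0


class TestSources:
    def _fields(self, **kw):
        base = dict(n=1.0, g=1.0, tgf=0.0, taf=0.0, m=0.0, F_E=0.0,
                    phi_V=0.5, phi_D=0.0, phi_E=0.35, B_nE=0.2, L_nE=0.2,
                    p=0.0)
        base.update(kw)
        return {k: np.array([v]) for k, v in base.items()}

    def test_normoxic_mitosis(self):
        S = model.source_terms(self._fields(), np.array([0.5]), ModelParams())
        assert S["S_V"][0] == pytest.approx(0.5)  # 1*1*(1+0)*0.5

    def test_necrosis_below_viability(self):
        S = model.source_terms(self._fields(n=0.1), np.array([0.5]),
                               ModelParams())
        assert S["S_V"][0] == pytest.approx(-1.5)  # -3 * 0.5
        assert S["S_D"][0] == pytest.approx(1.5)   # same term, + sign

    def test_tgf_gate_closes_ecm_production(self):
        prm = ModelParams()
        f = self._fields(tgf=0.1, m=0.4, F_E=1.0)
        S = model.source_terms(f, np.array([0.5]), prm)
        # below tgf_FE = 0.2 the production gate is shut
        assert S["S_E"][0] == pytest.approx(-prm.lam_deE * 0.4 * 0.35)

    def test_vectorized_equals_scalar_loop(self):
        rng = np.random.default_rng(8)
        prm = ModelParams()
        N = 50
        fields = {k: rng.uniform(0, 1, N) for k in
                  ("n", "g", "tgf", "taf", "m", "F_E", "phi_V", "phi_D",
                   "phi_E", "B_nE", "L_nE", "p")}
        f_sp = rng.uniform(0.1, 0.8, N)
        S = model.source_terms(fields, f_sp, prm)
        for i in range(N):
            fi = {k: np.array([v[i]]) for k, v in fields.items()}
            Si = model.source_terms(fi, np.array([f_sp[i]]), prm)
            for key in S:
                assert S[key][i] == Si[key][0]


class TestQuasiSteady:
    def test_unit_vascular_supply_gives_unit_oxygen(self):
        # zero uptake, unit supply concentration, Dirichlet 1 -> n == 1
        prm = ModelParams(k_n2=(0.0, 0.0, 0.0))
        h = hier(8, n_global=2)
        cfg = SolverConfig(tol_min=1e-11, max_outer_cycles=100)
        names = ["phi_V", "phi_D", "phi_E", "B_nE", "n", "g", "tgf", "taf"]
        h.alloc(names)
        for kappa in h.kappas():
            for b in h.level(kappa).blocks:
                b.data["phi_E"][...] = 0.5
                b.data["B_nE"][...] = 2.0  # supply n_C = B_nE*phi_E = 1
                b.data["n"][...] = 0.3     # start away from the solution
                b.data["g"][...] = 1.0
        model.quasi_steady_species_system(h, prm, cfg, tol=1e-11)
        for kappa in h.kappas():
            for b in h.level(kappa).blocks:
                assert np.allclose(b.interior("n"), 1.0, atol=1e-8)

    def test_all_rates_zero_gives_boundary_constant(self):
        prm = ModelParams(k_n2=(0, 0, 0), lam_B_n=(0, 0, 0))
        h = hier(8, n_global=2)
        cfg = SolverConfig(tol_min=1e-11, max_outer_cycles=200)
        h.alloc(["phi_V", "phi_D", "phi_E", "B_nE", "n", "g", "tgf", "taf"])
        for kappa in h.kappas():
            for b in h.level(kappa).blocks:
                b.data["n"][...] = 0.5
                b.data["g"][...] = 1.0
        model.quasi_steady_species_system(h, prm, cfg, tol=1e-11)
        b = h.level(0).blocks[0]
        assert np.allclose(b.interior("n"), 1.0, atol=1e-8)

    def test_oxygen_matches_dense_direct_solve(self):
        prm = ModelParams()
        h = hier(8, n_global=2)
        cfg = SolverConfig(tol_min=1e-12, max_outer_cycles=300)
        h.alloc(["phi_V", "phi_D", "phi_E", "B_nE", "n", "g", "tgf", "taf"])
        rng = np.random.default_rng(12)
        for kappa in h.kappas():
            for b in h.level(kappa).blocks:
                b.data["phi_E"][...] = 0.35
                b.data["B_nE"][...] = 0.2
        b = h.level(0).blocks[0]
        b.interior("phi_V")[...] = rng.uniform(0, 0.6, b.shape)
        tr.restrict_level_to_coarse(h, 0, ["phi_V"])
        tr.fill_level_ghosts(h, 0, model.bc_table(prm))
        tr.fill_level_ghosts(h, -1, model.bc_table(prm))
        model.quasi_steady_species_system(h, prm, cfg, tol=1e-12)
        # dense oracle with the same coefficients and ghost convention
        n_ = 8
        eta = h.level(0).eta
        f = b.data
        phiT = f["phi_V"] + f["phi_D"]
        acoef = (model.effective_coefficient(phiT, f["phi_E"], *prm.lam_B_n)
                 + model.effective_coefficient(phiT, f["phi_E"], *prm.k_n2))
        dcoef = model.effective_coefficient(phiT, f["phi_E"], *prm.D_n)
        rhs = (model.effective_coefficient(phiT, f["phi_E"], *prm.lam_B_n)
               * f["B_nE"] * f["phi_E"])
        A = sp.lil_matrix((n_**3, n_**3))
        bvec = np.zeros(n_**3)

        def idx(i, j, k):
            return ((i - 1) * n_ + (j - 1)) * n_ + (k - 1)

        for i in range(1, n_ + 1):
            for j in range(1, n_ + 1):
                for k in range(1, n_ + 1):
                    r = idx(i, j, k)
                    A[r, r] = acoef[i, j, k]
                    bvec[r] = rhs[i, j, k]
                    for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        ii, jj, kk = i + di, j + dj, k + dk
                        Df = 0.5 * (dcoef[i, j, k] + dcoef[ii, jj, kk])
                        if 1 <= ii <= n_ and 1 <= jj <= n_ and 1 <= kk <= n_:
                            A[r, r] += Df / eta**2
                            A[r, idx(ii, jj, kk)] = -Df / eta**2
                        else:  # ghost = 2*1 - interior
                            A[r, r] += 2 * Df / eta**2
                            bvec[r] += 2 * Df / eta**2 * 1.0
        want = spla.spsolve(A.tocsr(), bvec).reshape(n_, n_, n_)
        assert np.max(np.abs(b.interior("n") - want)) < 1e-8

    def test_ion_closure_and_zero_guard(self):
        prm = ModelParams()
        h = hier(8, n_global=1)
        cfg = SolverConfig(tol_min=1e-8, max_outer_cycles=100)
        h.alloc(["phi_V", "phi_D", "phi_E", "B_nE", "n", "g", "tgf", "taf",
                 "w", "l", "b", "a", "s", "r"])
        for b_ in h.level(0).blocks:
            b_.data["phi_E"][...] = 0.35
            b_.data["n"][...] = 1.0
            b_.data["g"][...] = 1.0
        model.quasi_steady_species_system(h, prm, cfg, with_ions=True,
                                          tol=1e-8, picard_iters=3)
        blk = h.level(0).blocks[0]
        for nm in ("w", "l", "b", "a", "s", "r"):
            assert np.isfinite(blk.data[nm]).all()
        # electroneutrality closure
        f = blk.data
        want = -(prm.z_l * f["l"] + prm.z_b * f["b"] + prm.z_a * f["a"]
                 + prm.z_s * f["s"]) / prm.z_r
        assert np.allclose(f["r"], want, atol=1e-12)
        # all-zero charged concentrations give r = 0 without dividing by 0
        for nm in ("l", "b", "a", "s"):
            f[nm][...] = 0.0
        f["r"][...] = -(prm.z_l * f["l"] + prm.z_b * f["b"]
                        + prm.z_a * f["a"] + prm.z_s * f["s"]) / prm.z_r
        assert np.all(f["r"] == 0.0)


class TestBoundaryConditions:
    def test_bc_table_values(self):
        prm = ModelParams()
        t = model.bc_table(prm)
        assert t["phi_V"][0] == "neumann"
        assert t["n"] == ("dirichlet", 1.0)
        assert t["B_nE"] == ("dirichlet", 0.2)
        assert t["mu_T"] == ("dirichlet", 0.0)

    def test_apply_bcs_ghost_values(self):
        prm = ModelParams()
        h = hier(4)
        h.level(0).alloc(["phi_V", "n", "B_nE"])
        b = h.level(0).blocks[0]
        b.data["phi_V"][...] = 0.65
        b.data["n"][...] = 0.8
        b.data["B_nE"][...] = 0.3
        model.apply_bcs(h, 0, prm)
        assert b.data["phi_V"][0, 2, 2] == pytest.approx(0.65)
        assert b.data["n"][0, 2, 2] == pytest.approx(1.2)
        assert b.data["B_nE"][0, 2, 2] == pytest.approx(0.1)


class TestTransientFluxes:
    def _setup(self, taf, phiE, tgf, uE=0.0):
        prm = ModelParams()
        h = hier(8)
        h.level(0).alloc(["F_E", "B_nE", "L_nE", "tgf", "taf", "phi_E"])
        b = h.level(0).blocks[0]
        rng = np.random.default_rng(4)
        b.data["F_E"][...] = rng.uniform(0.1, 0.5, b.data["F_E"].shape)
        b.data["B_nE"][...] = rng.uniform(0.1, 0.3, b.data["B_nE"].shape)
        b.data["L_nE"][...] = 0.2
        b.data["taf"][...] = taf
        b.data["tgf"][...] = tgf
        b.data["phi_E"][...] = phiE
        b.alloc_faces(["u_E"], fill=uE)
        b.face_data["u_E"] = b.face_data["u_E"]
        return prm, h, b

    def test_uniform_taf_and_ecm_leave_only_diffusion(self):
        prm, h, b = self._setup(taf=0.3, phiE=0.35, tgf=0.0, uE=0.0)
        out = model.transient_species_rhs(h, 0, prm)
        assert np.allclose(out[id(b)]["B_nE"], 0.0, atol=1e-13)

    def test_uniform_tgf_gives_pure_advection_for_myofibroblasts(self):
        import tumormg.stencil as st
        prm, h, b = self._setup(taf=0.0, phiE=0.35, tgf=0.2, uE=0.05)
        out = model.transient_species_rhs(h, 0, prm)
        want = -st.upwind_div(b.data["F_E"], b.face_data["u_E"],
                              h.level(0).eta)
        assert np.allclose(out[id(b)]["F_E"], want, atol=1e-13)


class TestElasticity:
    def test_derivative_vanishes_at_pure_phases(self):
        from tumormg.elastic import elastic_derivative
        prm = ModelParams(eps_e=1.0, Estar_E=0.1)
        h = hier(4)
        h.level(0).alloc(["phi_E"])
        b = h.level(0).blocks[0]
        for val in (0.0, 1.0):
            b.data["phi_E"][...] = val
            dW = elastic_derivative(b, prm, h.level(0).eta)
            assert np.allclose(dW, 0.0, atol=1e-14)

    def test_zero_eigenstrain_gives_zero_displacement(self):
        from tumormg.elastic import solve_displacement, elastic_state
        prm = ModelParams(eps_e=1.0, Estar_E=0.0, Estar_C=0.0)
        h = hier(4)
        h.level(0).alloc(["phi_E"])
        b = h.level(0).blocks[0]
        b.data["phi_E"][...] = 0.35
        solve_displacement(h, prm)
        for k in range(3):
            assert np.allclose(b.data[f"ud_{k}"], 0.0, atol=1e-12)
        s = elastic_state(b, prm, h.level(0).eta)
        assert np.allclose(s["T"], 0.0, atol=1e-12)

    def test_nonpositive_lame_rejected(self):
        from tumormg.elastic import solve_displacement
        prm = ModelParams(L2E=0.0)
        h = hier(4)
        with pytest.raises(ValueError):
            solve_displacement(h, prm)

    def test_stress_is_symmetric_with_displacement(self):
        from tumormg.elastic import solve_displacement, elastic_state
        prm = ModelParams(eps_e=1.0, Estar_E=0.05, L1E=2.0, L2E=1.5)
        h = hier(4)
        h.level(0).alloc(["phi_E"])
        b = h.level(0).blocks[0]
        x = [(np.arange(l - 1, hi + 2) - 0.5) * h.level(0).eta
             for l, hi in zip(b.lo, b.hi)]
        X, Y, Z = np.meshgrid(*x, indexing="ij")
        b.data["phi_E"][...] = 0.3 + 0.2 * np.sin(2 * np.pi * X)
        solve_displacement(h, prm)
        s = elastic_state(b, prm, h.level(0).eta)
        T = s["T"]
        for m in range(3):
            for n_ in range(3):
                assert np.allclose(T[m, n_], T[n_, m], atol=1e-12)
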