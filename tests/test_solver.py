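"""Multigrid machinery: smoother oracles, FAS two-grid equivalence,
mesh-independent convergence, FMG accuracy, Crank-Nicolson vs dense solve."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from tumormg.mesh import Block, build_hierarchy, count_dof
from tumormg import transfer as tr
from tumormg.solver import (
    CahnHilliardScalarSystem,
    ScalarLinearSystem,
    SolverConfig,
    adapfas_cycle,
    residual_norm,
    smooth,
    solve_scalar,
    fmg_solve,
)


def poisson_hierarchy(n, n_global=1, kappa_max=0):
    """-lap(u) = f on (0,1)^3, u = 0 on the boundary."""
    h = build_hierarchy([(0.0, 1.0)] * 3, (n,) * 3, n_global, kappa_max)
    for kappa in h.kappas():
        for b in h.level(kappa).blocks:
            b.alloc(["u", "coef_a_u", "coef_d_u", "rhs_u"])
            b.data["coef_d_u"][...] = 1.0
    return h


def mms_fields(h, kappa):
    lev = h.level(kappa)
    b = lev.blocks[0]
    x = [np.arange(l, hi + 1) - 0.5 for l, hi in zip(b.lo, b.hi)]
    X, Y, Z = np.meshgrid(*[xi * lev.eta for xi in x], indexing="ij")
    u = np.sin(np.pi * X) * np.sin(np.pi * Y) * np.sin(np.pi * Z)
    f = 3 * np.pi**2 * u
    return u, f


def dense_poisson_matrix(n, eta, a_coef=0.0, d_coef=1.0):
    """Sparse operator of a u - d div(grad u) with the cell-centered
    Dirichlet ghost convention (ghost = -interior)."""
    N = n**3

    def idx(i, j, k):
        return (i * n + j) * n + k

    rows, cols, vals = [], [], []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                r = idx(i, j, k)
                diag = a_coef + 6.0 * d_coef / eta**2
                for (di, dj, dk) in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                     (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if 0 <= ii < n and 0 <= jj < n and 0 <= kk < n:
                        rows.append(r)
                        cols.append(idx(ii, jj, kk))
                        vals.append(-d_coef / eta**2)
                    else:
                        diag += d_coef / eta**2  # ghost = -interior
                rows.append(r)
                cols.append(r)
                vals.append(diag)
    return sp.csr_matrix((vals, (rows, cols)), shape=(N, N))


class TestSmoother:
    def test_matches_scalar_loop_oracle_and_reduces_residual(self):
        n = 6
        h = poisson_hierarchy(n)
        b = h.level(0).blocks[0]
        u_ms, f = mms_fields(h, 0)
        rng = np.random.default_rng(5)
        b.interior("u")[...] = rng.normal(size=(n, n, n))
        b.interior("rhs_u")[...] = f
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        tr.fill_level_ghosts(h, 0, sys_.bc_map())
        oracle = b.data["u"].copy()
        eta = h.level(0).eta
        cfg = SolverConfig(nu_b=0)
        r0 = residual_norm(h, sys_, 0)
        smooth(h, sys_, 0, 2, cfg)
        # independent scalar-loop red-black Gauss-Seidel
        for sweep in range(2):
            for color in (0, 1):
                for i in range(1, n + 1):
                    for j in range(1, n + 1):
                        for k in range(1, n + 1):
                            if (i + j + k) % 2 != color:
                                continue
                            nb = (oracle[i + 1, j, k] + oracle[i - 1, j, k]
                                  + oracle[i, j + 1, k] + oracle[i, j - 1, k]
                                  + oracle[i, j, k + 1] + oracle[i, j, k - 1])
                            oracle[i, j, k] = ((f[i - 1, j - 1, k - 1]
                                                + nb / eta**2)
                                               / (6.0 / eta**2))
            # ghost refresh (Dirichlet 0)
            for a in range(3):
                sl = [slice(1, -1)] * 3
                si = [slice(1, -1)] * 3
                sl[a], si[a] = 0, 1
                oracle[tuple(sl)] = -oracle[tuple(si)]
                sl[a], si[a] = -1, -2
                oracle[tuple(sl)] = -oracle[tuple(si)]
        assert np.allclose(b.data["u"][1:-1, 1:-1, 1:-1],
                           oracle[1:-1, 1:-1, 1:-1], atol=1e-13)
        assert residual_norm(h, sys_, 0) < r0

    def test_exact_solution_is_fixed_point(self):
        n = 8
        h = poisson_hierarchy(n)
        b = h.level(0).blocks[0]
        eta = h.level(0).eta
        A = dense_poisson_matrix(n, eta)
        _, f = mms_fields(h, 0)
        u_star = spla.spsolve(A, f.ravel()).reshape(n, n, n)
        b.interior("u")[...] = u_star
        b.interior("rhs_u")[...] = f
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        tr.fill_level_ghosts(h, 0, sys_.bc_map())
        before = b.interior("u").copy()
        sys_.relax_once(h, 0)
        assert np.allclose(b.interior("u"), before, atol=1e-11)

    def test_zero_sweeps_is_identity(self):
        n = 4
        h = poisson_hierarchy(n)
        b = h.level(0).blocks[0]
        rng = np.random.default_rng(0)
        b.interior("u")[...] = rng.normal(size=(n, n, n))
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        tr.fill_level_ghosts(h, 0, sys_.bc_map())
        before = b.interior("u").copy()
        smooth(h, sys_, 0, 0, SolverConfig(nu_b=0))
        assert np.array_equal(b.interior("u"), before)


class TestResidualNorm:
    def test_exact_solution_gives_zero(self):
        n = 6
        h = poisson_hierarchy(n)
        b = h.level(0).blocks[0]
        A = dense_poisson_matrix(n, h.level(0).eta)
        _, f = mms_fields(h, 0)
        b.interior("u")[...] = spla.spsolve(A, f.ravel()).reshape(n, n, n)
        b.interior("rhs_u")[...] = f
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        tr.fill_level_ghosts(h, 0, sys_.bc_map())
        assert residual_norm(h, sys_, 0) < 1e-11

    def test_constant_residual_gives_its_magnitude(self):
        n = 6
        h = poisson_hierarchy(n)
        b = h.level(0).blocks[0]
        rng = np.random.default_rng(2)
        b.interior("u")[...] = rng.normal(size=(n, n, n))
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        tr.fill_level_ghosts(h, 0, sys_.bc_map())
        L = sys_.apply_operator(h, 0, b)["u"]
        b.interior("rhs_u")[...] = L - 0.7
        assert residual_norm(h, sys_, 0) == pytest.approx(0.7, abs=1e-12)

    def test_random_residual_matches_dense_norm(self):
        n = 5
        h = poisson_hierarchy(n)
        b = h.level(0).blocks[0]
        rng = np.random.default_rng(9)
        b.interior("u")[...] = rng.normal(size=(n, n, n))
        b.interior("rhs_u")[...] = rng.normal(size=(n, n, n))
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        tr.fill_level_ghosts(h, 0, sys_.bc_map())
        res = sys_.residuals(h, 0, b)["u"]
        want = np.sqrt((res**2).sum() / n**3)
        assert residual_norm(h, sys_, 0) == pytest.approx(want, rel=1e-13)


class TestAdapFAS:
    def test_single_level_cycle_equals_smoothing(self):
        n = 6
        cfg = SolverConfig(nu_b=0, nu1=2, nu2=1)
        h1 = poisson_hierarchy(n)
        h2 = poisson_hierarchy(n)
        _, f = mms_fields(h1, 0)
        rng = np.random.default_rng(4)
        u0 = rng.normal(size=(n, n, n))
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        for h in (h1, h2):
            b = h.level(0).blocks[0]
            b.interior("u")[...] = u0
            b.interior("rhs_u")[...] = f
            tr.fill_level_ghosts(h, 0, sys_.bc_map())
        adapfas_cycle(h1, sys_, 0, cfg)
        smooth(h2, sys_, 0, cfg.nu1 + cfg.nu2, cfg)
        assert np.array_equal(h1.level(0).blocks[0].data["u"],
                              h2.level(0).blocks[0].data["u"])

    def test_two_grid_cycle_matches_dense_fas_oracle(self):
        """Adaptive two-level cycle on an everything-flagged mesh ==
        classical two-grid FAS from an independent dense implementation."""
        n_c, n_f = 8, 16
        cfg = SolverConfig(nu_b=0, nu0=4, nu1=2, nu2=2)
        h = poisson_hierarchy(n_c, n_global=1, kappa_max=1)
        fineb = Block((1, 1, 1), (n_f, n_f, n_f))
        fineb.alloc(["u", "coef_a_u", "coef_d_u", "rhs_u"])
        fineb.data["coef_d_u"][...] = 1.0
        h.level(1).blocks.append(fineb)
        _, f_f = mms_fields(h, 1)
        _, f_c = mms_fields(h, 0)
        rng = np.random.default_rng(11)
        u0 = rng.normal(size=(n_f,) * 3)
        fineb.interior("u")[...] = u0
        fineb.interior("rhs_u")[...] = f_f
        h.level(0).blocks[0].interior("rhs_u")[...] = f_c
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        tr.fill_level_ghosts(h, 0, sys_.bc_map())
        tr.fill_level_ghosts(h, 1, sys_.bc_map())
        adapfas_cycle(h, sys_, 1, cfg)
        got = fineb.interior("u").copy()

        # ---- dense oracle ------------------------------------------------
        eta_f = 1.0 / n_f
        eta_c = 1.0 / n_c

        def pad_dir(ui):
            # sequential full-slab odd reflection (corners get the double
            # reflection, as the cell-centered Dirichlet convention implies)
            arr = np.zeros(tuple(s + 2 for s in ui.shape))
            arr[1:-1, 1:-1, 1:-1] = ui
            for a in range(3):
                sl = [slice(None)] * 3
                si = [slice(None)] * 3
                sl[a], si[a] = 0, 1
                arr[tuple(sl)] = -arr[tuple(si)]
                sl[a], si[a] = -1, -2
                arr[tuple(sl)] = -arr[tuple(si)]
            return arr

        def rbgs(ui, f, eta, sweeps):
            arr = pad_dir(ui)
            n = ui.shape[0]
            for _ in range(sweeps):
                for color in (0, 1):
                    for i in range(1, n + 1):
                        for j in range(1, n + 1):
                            for k in range(1, n + 1):
                                if (i + j + k) % 2 != color:
                                    continue
                                nb = (arr[i + 1, j, k] + arr[i - 1, j, k]
                                      + arr[i, j + 1, k] + arr[i, j - 1, k]
                                      + arr[i, j, k + 1] + arr[i, j, k - 1])
                                arr[i, j, k] = ((f[i - 1, j - 1, k - 1]
                                                 + nb / eta**2)
                                                / (6.0 / eta**2))
                arr = pad_dir(arr[1:-1, 1:-1, 1:-1])
            return arr[1:-1, 1:-1, 1:-1]

        def lap_apply(ui, eta):
            arr = pad_dir(ui)
            return -(arr[2:, 1:-1, 1:-1] + arr[:-2, 1:-1, 1:-1]
                     + arr[1:-1, 2:, 1:-1] + arr[1:-1, :-2, 1:-1]
                     + arr[1:-1, 1:-1, 2:] + arr[1:-1, 1:-1, :-2]
                     - 6 * ui) / eta**2

        def restrict(ui):
            return ui.reshape(n_c, 2, n_c, 2, n_c, 2).mean(axis=(1, 3, 5))

        u = rbgs(u0, f_f, eta_f, cfg.nu1)
        res = f_f - lap_apply(u, eta_f)
        psi0 = restrict(u)
        Rc = restrict(res) + lap_apply(psi0, eta_c)
        psi = rbgs(psi0, Rc, eta_c, cfg.nu0)
        e = pad_dir(psi) - pad_dir(psi0)
        ef = tr.prolong_linear(e)
        u = u + ef
        u = rbgs(u, f_f, eta_f, cfg.nu2)
        assert np.max(np.abs(got - u)) < 1e-9

    def test_exact_iterate_yields_zero_correction(self):
        n = 8
        cfg = SolverConfig(nu_b=0, nu1=0, nu2=0, nu0=0)
        h = poisson_hierarchy(n, n_global=2)
        b = h.level(0).blocks[0]
        eta = h.level(0).eta
        _, f = mms_fields(h, 0)
        A = dense_poisson_matrix(n, eta)
        u_star = spla.spsolve(A, f.ravel()).reshape(n, n, n)
        b.interior("u")[...] = u_star
        b.interior("rhs_u")[...] = f
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        tr.fill_level_ghosts(h, 0, sys_.bc_map())
        # with no smoothing at all, the coarse equation is already satisfied
        # by the restricted iterate, so the cycle must not change psi
        adapfas_cycle(h, sys_, 0, cfg)
        assert np.allclose(b.interior("u"), u_star, atol=1e-11)


class TestMultigridHealth:
    def cycles_to_tol(self, n, tol=1e-8):
        cfg = SolverConfig()
        # coarsen down to a 2^3 coarsest grid so the nu0-sweep bottom solve
        # is effectively exact at every problem size
        n_global = int(np.log2(n)) - 1
        h = poisson_hierarchy(n, n_global=n_global)
        for kappa in range(h.kappa_min, 1):
            _, fc = mms_fields(h, kappa)
            h.level(kappa).blocks[0].interior("rhs_u")[...] = fc
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        for kappa in h.kappas():
            tr.fill_level_ghosts(h, kappa, sys_.bc_map())
        it = 0
        while residual_norm(h, sys_, 0) > tol:
            adapfas_cycle(h, sys_, 0, cfg)
            it += 1
            assert it < 60
        return it

    def test_cycle_count_is_mesh_independent(self):
        counts = [self.cycles_to_tol(n) for n in (8, 16, 32)]
        assert max(counts) - min(counts) <= 2

    def test_fmg_reaches_second_order_accuracy(self):
        errs = []
        for n in (8, 16, 32):
            cfg = SolverConfig(tol_min=1e-10, max_outer_cycles=100)
            h = poisson_hierarchy(n, n_global=3)
            sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
            for kappa in h.kappas():
                _, fc = mms_fields(h, kappa)
                h.level(kappa).blocks[0].interior("rhs_u")[...] = fc
                tr.fill_level_ghosts(h, kappa, sys_.bc_map())
            fmg_solve(h, sys_, cfg)
            u_ms, _ = mms_fields(h, 0)
            diff = h.level(0).blocks[0].interior("u") - u_ms
            errs.append(np.sqrt((diff**2).mean()))
        r1 = np.log2(errs[0] / errs[1])
        r2 = np.log2(errs[1] / errs[2])
        assert r1 > 1.7 and r2 > 1.7


class TestCrankNicolson:
    def test_heat_step_matches_dense_oracle(self):
        n = 8
        theta = 0.01
        h = poisson_hierarchy(n)
        b = h.level(0).blocks[0]
        eta = h.level(0).eta
        rng = np.random.default_rng(21)
        u0 = rng.normal(size=(n, n, n))
        # CN right-hand side: u0/theta + (1/2) lap(u0)
        pad = np.zeros((n + 2,) * 3)
        pad[1:-1, 1:-1, 1:-1] = u0
        for a in range(3):
            sl = [slice(1, -1)] * 3
            si = [slice(1, -1)] * 3
            sl[a], si[a] = 0, 1
            pad[tuple(sl)] = -pad[tuple(si)]
            sl[a], si[a] = -1, -2
            pad[tuple(sl)] = -pad[tuple(si)]
        lap0 = (pad[2:, 1:-1, 1:-1] + pad[:-2, 1:-1, 1:-1]
                + pad[1:-1, 2:, 1:-1] + pad[1:-1, :-2, 1:-1]
                + pad[1:-1, 1:-1, 2:] + pad[1:-1, 1:-1, :-2]
                - 6 * u0) / eta**2
        rhs = u0 / theta + 0.5 * lap0
        b.data["coef_a_u"][...] = 1.0 / theta
        b.data["coef_d_u"][...] = 0.5
        b.interior("rhs_u")[...] = rhs
        b.interior("u")[...] = u0
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        cfg = SolverConfig(tol_min=1e-12, max_outer_cycles=200)
        solve_scalar(h, sys_, cfg, tol=1e-12)
        A = dense_poisson_matrix(n, eta, a_coef=1.0 / theta, d_coef=0.5)
        want = spla.spsolve(A, rhs.ravel()).reshape(n, n, n)
        assert np.max(np.abs(b.interior("u") - want)) < 1e-10


    def test_vanishing_time_step_returns_identity(self):
        # as theta -> 0 the CN update is dominated by u/theta = u0/theta
        n = 6
        theta = 1e-12
        h = poisson_hierarchy(n)
        b = h.level(0).blocks[0]
        rng = np.random.default_rng(7)
        u0 = rng.normal(size=(n, n, n))
        b.data["coef_a_u"][...] = 1.0 / theta
        b.data["coef_d_u"][...] = 0.5
        b.interior("u")[...] = u0
        b.interior("rhs_u")[...] = u0 / theta
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        # the residual scales as 1/theta, so tol=1 bounds |u-u0| by theta
        solve_scalar(h, sys_, SolverConfig(theta=theta), tol=1.0)
        assert np.allclose(b.interior("u"), u0, atol=1e-9)


class TestCahnHilliardFixture:
    def test_mass_conserved_over_ten_steps(self):
        # theta must resolve the interfacial time scale for plain CN
        n = 16
        theta = 1e-3
        h = build_hierarchy([(0.0, 1.0)] * 3, (n,) * 3, 3, kappa_max=0)
        sys_ = CahnHilliardScalarSystem(theta=theta, eps=0.1, A=1.0)
        for kappa in h.kappas():
            h.level(kappa).alloc(["phi", "mu", "rhs_phi", "rhs_mu"])
        b = h.level(0).blocks[0]
        x = (np.arange(n) + 0.5) / n
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        b.interior("phi")[...] = 0.5 + 0.2 * np.cos(2 * np.pi * X) \
            * np.cos(2 * np.pi * Y) * np.cos(np.pi * Z)
        tr.restrict_level_to_coarse(h, 0, ["phi"])
        mass0 = b.interior("phi").sum()
        cfg = SolverConfig(tol_min=1e-9, max_outer_cycles=100)
        for _ in range(10):
            for kappa in h.kappas():
                tr.fill_level_ghosts(h, kappa, sys_.bc_map())
                lev = h.level(kappa)
                for blk in lev.blocks:
                    lap_mu0 = 0.0  # mu unknown; CN rhs uses old phi, mu
                    import tumormg.stencil as st
                    blk.interior("rhs_phi")[...] = (
                        blk.interior("phi") / theta
                        + 0.5 * sys_.M * st.laplacian(blk.data["mu"],
                                                      lev.eta))
                    blk.interior("rhs_mu")[...] = 0.0
            # initialise mu consistently at the first step
            solve_scalar(h, sys_, cfg, tol=1e-9)
        mass = b.interior("phi").sum()
        assert abs(mass - mass0) / abs(mass0) < 1e-6
        assert np.isfinite(b.interior("phi")).all()
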