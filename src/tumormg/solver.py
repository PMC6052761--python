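"""Crank-Nicolson time discretization and the adaptive nonlinear FAS-FMG
multigrid machinery.

Each time step looks for the fixed point of a level-wise nonlinear system
``L_k(psi) = R_k`` assembled by :func:`crank_nicolson_system`: the
fourth-order Cahn-Hilliard cell/ECM equations are split into coupled
second-order pairs (volume fractions and chemical potentials, solved
simultaneously), transient terms are averaged between the old and new time
levels, and advection, sources, and the surface-adhesion cross terms are
taken explicitly at the old time level.

The solve itself is a full multigrid (FMG) iteration over the block-
structured hierarchy: nested iteration from the coarsest global grid upward,
cubic interpolation providing each finer level's initial guess, and
adaptive Full Approximation Scheme (FAS) V-cycles with tau-corrected coarse
right-hand sides on refined-level overlaps.  Error smoothing is nonlinear
red-black Gauss-Seidel: each cell's small coupled system is solved by a few
Newton steps on the diagonal block with neighboring cells frozen, with
extra sweeps in bands near block boundaries.  On levels ``kappa >= 0`` the
V-cycles repeat until the scaled residual norm drops below a per-level
tolerance ``tol_k = tol_min * sigma**(kappa_max - kappa)``; after a level
converges, the refinement criterion may grow the hierarchy by one level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stencil as st
from . import transfer as tr
from .mesh import MeshHierarchy
from .params import ModelParams

__all__ = [
    "SolverConfig",
    "SolverAbort",
    "DiscreteSystem",
    "ScalarLinearSystem",
    "CahnHilliardScalarSystem",
    "TumorSystem",
    "crank_nicolson_system",
    "smooth",
    "adapfas_cycle",
    "fmg_solve",
    "solve_scalar",
    "residual_norm",
]


@dataclass
class SolverConfig:
    """Multigrid control parameters plus time step and refinement criteria."""

    gamma: int = 1              # cycle index (1 = V, 2 = W)
    nu0: int = 4                # coarsest-level smoothing steps (= nu1+nu2)
    nu1: int = 2                # pre-correction smoothing steps
    nu2: int = 2                # post-correction smoothing steps
    nu_b: int = 2               # extra near-boundary smoothing steps
    r_kappa: int = 1            # V-cycles per level below the root level
    sigma: float = 4.0          # tolerance reduction factor per finer level
    tol_min: float = 5e-4       # tightest residual tolerance (finest level)
    theta: float = 1e-2         # time step size
    C_kappa: float = 0.05       # critical value of the undivided gradient test
    threshold_eff: float = 0.9
    threshold_size: int = 1000
    min_eff: float = 0.5
    buffer_radius: int = 4
    max_outer_cycles: int = 50
    flag_variable: str = "phi_T"
    newton_iters: int = 5
    newton_tol: float = 1e-11

    def __post_init__(self):
        if self.sigma <= 1:
            raise ValueError("sigma must exceed 1")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        for nm in ("nu0", "nu1", "nu2", "nu_b", "r_kappa", "gamma"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")

    def tol_level(self, kappa: int, kappa_max: int) -> float:
        """Residual tolerance schedule: tol reduced by sigma per finer level,
        with the minimum tolerance on the finest level."""
        return self.tol_min * self.sigma ** (kappa_max - kappa)

    def d_kappa(self, h: MeshHierarchy, kappa: int) -> int:
        """Near-boundary band depth: 2**(kappa - kappa_min) on global levels,
        1/8 of the minimum block dimension on refined levels."""
        if kappa <= 0:
            return 2 ** (kappa - h.kappa_min)
        dims = [min(b.shape) for b in h.level(kappa).blocks]
        return max(1, min(dims) // 8) if dims else 0


class SolverAbort(RuntimeError):
    """Raised when the outer iteration cap is exceeded; carries the last
    residual report."""

    def __init__(self, msg, residuals=None):
        super().__init__(msg)
        self.residuals = residuals or {}


# ---------------------------------------------------------------------------
# systems
# ---------------------------------------------------------------------------

class DiscreteSystem:
    """Level-wise nonlinear operator bundle L(psi) = R.

    Subclasses define ``unknowns`` (block array names), their physical
    boundary conditions, a red-black relaxation, and the operator
    application used for residuals and the FAS tau correction.  Per-block
    right-hand sides live in ``rhs_<name>`` arrays.
    """

    unknowns: list[str] = []

    def bc_map(self) -> dict:
        raise NotImplementedError

    def relax_once(self, h, kappa, band: int = 0) -> None:
        raise NotImplementedError

    def apply_operator(self, h, kappa, block) -> dict:
        """L(psi) per unknown on one block (interior arrays); ghosts must
        be current."""
        raise NotImplementedError

    # -- shared helpers -----------------------------------------------------
    def residuals(self, h, kappa, block) -> dict:
        L = self.apply_operator(h, kappa, block)
        return {u: st.interior(block.data[f"rhs_{u}"]) - L[u]
                for u in self.unknowns}

    @staticmethod
    def color_mask(block, color: int) -> np.ndarray:
        """Checkerboard mask in global index parity (red = even i+j+k)."""
        grids = np.meshgrid(*[np.arange(l, h_ + 1)
                              for l, h_ in zip(block.lo, block.hi)],
                            indexing="ij")
        parity = sum(grids) % 2
        return parity == color

    @staticmethod
    def band_mask(block, d: int) -> np.ndarray:
        """Cells within ``d`` of any block face."""
        mask = np.zeros(block.shape, dtype=bool)
        for a in range(block.ndim):
            sl = [slice(None)] * block.ndim
            sl[a] = slice(0, d)
            mask[tuple(sl)] = True
            sl[a] = slice(-d, None)
            mask[tuple(sl)] = True
        return mask


class ScalarLinearSystem(DiscreteSystem):
    """One linear reaction-diffusion unknown: L(u) = a u - div(D grad u).

    Per-block arrays: ``coef_a_<name>``, ``coef_d_<name>`` (cell-centered,
    ghosts valid), and ``rhs_<name>``.  Used for the pressure and
    quasi-steady species solves and for the Poisson/heat fixtures.
    """

    def __init__(self, name: str, bc):
        self.name = name
        self.unknowns = [name]
        self._bc = {name: bc}

    def bc_map(self):
        return dict(self._bc)

    def _faces(self, block):
        D = block.data[f"coef_d_{self.name}"]
        return [st.face_avg(D, a) for a in range(block.ndim)]

    def _neighbor_terms(self, block, eta):
        """(sum_f D_f u_nb, sum_f D_f) / eta^2 as interior arrays."""
        u = block.data[self.name]
        nd = block.ndim
        Df = self._faces(block)
        num = 0.0
        den = 0.0
        for a in range(nd):
            lo_idx = [slice(None)] * nd
            hi_idx = [slice(None)] * nd
            lo_idx[a] = slice(0, -1)
            hi_idx[a] = slice(1, None)
            D_lo = Df[a][tuple(lo_idx)]
            D_hi = Df[a][tuple(hi_idx)]
            u_lo = st._ax(u, a, slice(0, -2))
            u_hi = st._ax(u, a, slice(2, None))
            num = num + (D_lo * u_lo + D_hi * u_hi)
            den = den + (D_lo + D_hi)
        return num / eta**2, den / eta**2

    def relax_once(self, h, kappa, band: int = 0):
        lev = h.level(kappa)
        for b in lev.blocks:
            a_c = st.interior(b.data[f"coef_a_{self.name}"])
            rhs = st.interior(b.data[f"rhs_{self.name}"])
            bmask = self.band_mask(b, band) if band else None
            for color in (0, 1):
                num, den = self._neighbor_terms(b, lev.eta)
                mask = self.color_mask(b, color)
                if bmask is not None:
                    mask = mask & bmask
                upd = (rhs + num) / (a_c + den)
                ui = b.interior(self.name)
                ui[mask] = upd[mask]

    def apply_operator(self, h, kappa, block):
        eta = h.level(kappa).eta
        num, den = self._neighbor_terms(block, eta)
        u = st.interior(block.data[self.name])
        a_c = st.interior(block.data[f"coef_a_{self.name}"])
        return {self.name: a_c * u - (num - den * u)}


class CahnHilliardScalarSystem(DiscreteSystem):
    """Single-species Cahn-Hilliard fixture, Crank-Nicolson in time.

    Unknowns (phi, mu) with constant mobility and no-flux boundaries::

        phi/theta - (1/2) div(M grad mu)          = R_phi
        mu - f'(phi) + eps^2 lap(phi)             = 0

    with the quartic double well f = A phi^2 (1-phi)^2.  Conserves the
    total mass of phi up to the solver tolerance.
    """

    unknowns = ["phi", "mu"]

    def __init__(self, theta: float, mobility: float = 1.0,
                 eps: float = 1.0, A: float = 1.0):
        self.theta = theta
        self.M = mobility
        self.eps = eps
        self.A = A

    def bc_map(self):
        return {"phi": ("neumann", None), "mu": ("neumann", None)}

    def fprime(self, v):
        return 2.0 * self.A * v * (1.0 - v) * (1.0 - 2.0 * v)

    def fsecond(self, v):
        return 2.0 * self.A * (1.0 - 6.0 * v + 6.0 * v * v)

    def relax_once(self, h, kappa, band: int = 0):
        lev = h.level(kappa)
        eta2 = lev.eta**2
        nd = h.ndim
        cdiag = 2.0 * nd / eta2
        for b in lev.blocks:
            R1 = st.interior(b.data["rhs_phi"])
            R2 = st.interior(b.data["rhs_mu"])
            bmask = self.band_mask(b, band) if band else None
            for color in (0, 1):
                mu_nb = st.neighbor_sum(b.data["mu"]) / eta2
                phi_nb = st.neighbor_sum(b.data["phi"]) / eta2
                mask = self.color_mask(b, color)
                if bmask is not None:
                    mask = mask & bmask
                v = b.interior("phi")[mask]
                mu = b.interior("mu")[mask]
                r1 = R1[mask]
                r2 = R2[mask]
                nb_mu = mu_nb[mask]
                nb_phi = phi_nb[mask]
                cM = self.M * cdiag
                for _ in range(4):
                    F1 = v / self.theta + 0.5 * (cM * mu - self.M * nb_mu) - r1
                    F2 = (mu - self.fprime(v)
                          + self.eps**2 * (nb_phi - cdiag * v) - r2)
                    J11 = 1.0 / self.theta
                    J12 = 0.5 * cM
                    J21 = -self.fsecond(v) - self.eps**2 * cdiag
                    det = J11 * 1.0 - J12 * J21
                    dv = (-F1 * 1.0 + J12 * F2) / det
                    dmu = (-J11 * F2 + J21 * F1) / det
                    v = v + dv
                    mu = mu + dmu
                    if max(np.abs(dv).max(initial=0.0),
                           np.abs(dmu).max(initial=0.0)) < 1e-12:
                        break
                b.interior("phi")[mask] = v
                b.interior("mu")[mask] = mu

    def apply_operator(self, h, kappa, block):
        eta = h.level(kappa).eta
        phi = block.data["phi"]
        mu = block.data["mu"]
        L1 = (st.interior(phi) / self.theta
              - 0.5 * self.M * st.laplacian(mu, eta))
        L2 = (st.interior(mu) - self.fprime(st.interior(phi))
              + self.eps**2 * st.laplacian(phi, eta))
        return {"phi": L1, "mu": L2}


class TumorSystem(DiscreteSystem):
    """Coupled Crank-Nicolson system for (phi_V, phi_D, phi_E, mu_T, mu_E).

    Mobilities are frozen at the old time level (per-block ``Mob_V/D/E``
    cell arrays); advection, sources, and the adhesion cross terms live in
    the right-hand sides.  The smoother solves each cell's 5x5 diagonal
    block by Newton iteration with neighbors frozen (nonlinear red-black
    Gauss-Seidel); a Picard fallback handles the rare non-finite Newton
    update.
    """

    unknowns = ["phi_V", "phi_D", "phi_E", "mu_T", "mu_E"]

    def __init__(self, prm: ModelParams, theta: float,
                 newton_iters: int = 5, newton_tol: float = 1e-11):
        self.prm = prm
        self.theta = theta
        self.newton_iters = newton_iters
        self.newton_tol = newton_tol
        self.picard_fallbacks = 0

    def bc_map(self):
        return {"phi_V": ("neumann", None), "phi_D": ("neumann", None),
                "phi_E": ("neumann", None), "mu_T": ("dirichlet", 0.0),
                "mu_E": ("dirichlet", 0.0)}

    def _mob_terms(self, block, mob_name, u_name, eta):
        """(sum_f M_f u_nb, sum_f M_f)/eta^2 as interior arrays."""
        M = block.data[mob_name]
        u = block.data[u_name]
        nd = block.ndim
        num = 0.0
        den = 0.0
        for a in range(nd):
            Mf = st.face_avg(M, a)
            lo_idx = [slice(None)] * nd
            hi_idx = [slice(None)] * nd
            lo_idx[a] = slice(0, -1)
            hi_idx[a] = slice(1, None)
            M_lo = Mf[tuple(lo_idx)]
            M_hi = Mf[tuple(hi_idx)]
            num = num + (M_lo * st._ax(u, a, slice(0, -2))
                         + M_hi * st._ax(u, a, slice(2, None)))
            den = den + (M_lo + M_hi)
        return num / eta**2, den / eta**2

    def relax_once(self, h, kappa, band: int = 0):
        from .model import bulk_energy_derivatives, bulk_energy_hessian

        prm = self.prm
        lev = h.level(kappa)
        eta2 = lev.eta**2
        nd = h.ndim
        cdiag = 2.0 * nd / eta2
        th = self.theta
        for b in lev.blocks:
            R = {u: st.interior(b.data[f"rhs_{u}"]) for u in self.unknowns}
            bmask = self.band_mask(b, band) if band else None
            for color in (0, 1):
                numV, cV = self._mob_terms(b, "Mob_V", "mu_T", lev.eta)
                numD, cD = self._mob_terms(b, "Mob_D", "mu_T", lev.eta)
                numE, cE = self._mob_terms(b, "Mob_E", "mu_E", lev.eta)
                phiT_pad = b.data["phi_V"] + b.data["phi_D"]
                nbT = st.neighbor_sum(phiT_pad) / eta2
                nbE = st.neighbor_sum(b.data["phi_E"]) / eta2
                mask = self.color_mask(b, color)
                if bmask is not None:
                    mask = mask & bmask
                if not mask.any():
                    continue
                x = np.stack([b.interior(u)[mask] for u in self.unknowns],
                             axis=-1)
                r = np.stack([R[u][mask] for u in self.unknowns], axis=-1)
                sel = (numV[mask], cV[mask], numD[mask], cD[mask],
                       numE[mask], cE[mask], nbT[mask], nbE[mask])
                x = self._newton_cells(x, r, sel, cdiag, th, prm)
                for j, u in enumerate(self.unknowns):
                    b.interior(u)[mask] = x[..., j]

    def _newton_cells(self, x, r, sel, cdiag, th, prm):
        from .model import bulk_energy_derivatives, bulk_energy_hessian

        numV, cV, numD, cD, numE, cE, nbT, nbE = sel
        n = x.shape[0]
        J = np.zeros((n, 5, 5))
        J[:, 0, 0] = 1.0 / th
        J[:, 1, 1] = 1.0 / th
        J[:, 2, 2] = 1.0 / th
        J[:, 0, 3] = 0.5 * cV
        J[:, 1, 3] = 0.5 * cD
        J[:, 2, 4] = 0.5 * cE
        J[:, 3, 3] = 1.0
        J[:, 4, 4] = 1.0
        eT2, eE2 = prm.eps_T**2, prm.eps_E**2
        for _ in range(self.newton_iters):
            v, d, e, mt, me = (x[:, 0], x[:, 1], x[:, 2], x[:, 3], x[:, 4])
            phiT = v + d
            fT, fE = bulk_energy_derivatives(phiT, e, prm)
            F = np.empty_like(x)
            F[:, 0] = v / th + 0.5 * (cV * mt - numV) - r[:, 0]
            F[:, 1] = d / th + 0.5 * (cD * mt - numD) - r[:, 1]
            F[:, 2] = e / th + 0.5 * (cE * me - numE) - r[:, 2]
            F[:, 3] = mt - fT + eT2 * (nbT - cdiag * phiT) - r[:, 3]
            F[:, 4] = me - fE + eE2 * (nbE - cdiag * e) - r[:, 4]
            if np.abs(F).max() < self.newton_tol:
                break
            dTT, dTE, dET, dEE = bulk_energy_hessian(phiT, e, prm)
            J[:, 3, 0] = -dTT - eT2 * cdiag
            J[:, 3, 1] = -dTT - eT2 * cdiag
            J[:, 3, 2] = -dTE
            J[:, 4, 0] = -dET
            J[:, 4, 1] = -dET
            J[:, 4, 2] = -dEE - eE2 * cdiag
            try:
                dx = np.linalg.solve(J, -F[..., None])[..., 0]
            except np.linalg.LinAlgError:
                dx = None
            if dx is None or not np.isfinite(dx).all():
                # Picard fallback: solve with the linear part only
                self.picard_fallbacks += 1
                Jl = J.copy()
                Jl[:, 3, :3] = 0.0
                Jl[:, 4, :3] = 0.0
                Jl[:, 3, 0] = Jl[:, 3, 1] = -eT2 * cdiag
                Jl[:, 4, 2] = -eE2 * cdiag
                dx = np.linalg.solve(Jl, -F[..., None])[..., 0]
            x = x + dx
        return x

    def apply_operator(self, h, kappa, block):
        from .model import bulk_energy_derivatives

        prm = self.prm
        lev = h.level(kappa)
        th = self.theta
        numV, cV = self._mob_terms(block, "Mob_V", "mu_T", lev.eta)
        numD, cD = self._mob_terms(block, "Mob_D", "mu_T", lev.eta)
        numE, cE = self._mob_terms(block, "Mob_E", "mu_E", lev.eta)
        v = st.interior(block.data["phi_V"])
        d = st.interior(block.data["phi_D"])
        e = st.interior(block.data["phi_E"])
        mt = st.interior(block.data["mu_T"])
        me = st.interior(block.data["mu_E"])
        phiT_pad = block.data["phi_V"] + block.data["phi_D"]
        lapT = st.laplacian(phiT_pad, lev.eta)
        lapE = st.laplacian(block.data["phi_E"], lev.eta)
        fT, fE = bulk_energy_derivatives(v + d, e, prm)
        return {
            "phi_V": v / th + 0.5 * (cV * mt - numV),
            "phi_D": d / th + 0.5 * (cD * mt - numD),
            "phi_E": e / th + 0.5 * (cE * me - numE),
            "mu_T": mt - fT + prm.eps_T**2 * lapT,
            "mu_E": me - fE + prm.eps_E**2 * lapE,
        }


def crank_nicolson_system(h: MeshHierarchy, prm: ModelParams,
                          cfg: SolverConfig) -> TumorSystem:
    """Assemble the Crank-Nicolson system for one time step.

    Must be called while the block fields hold the previous-time solution
    with current ghosts, with old-time sources (``S_V/S_D/S_E``) and face
    velocities (``u_alpha``) in place.  Freezes the old-time mobilities and
    builds the per-level right-hand sides (see :func:`build_ch_rhs`).
    """
    system = TumorSystem(prm, cfg.theta, cfg.newton_iters, cfg.newton_tol)
    for kappa in h.kappas():
        if h.level(kappa).blocks:
            build_ch_rhs(h, kappa, prm, cfg)
    return system


def build_ch_rhs(h: MeshHierarchy, kappa: int, prm: ModelParams,
                 cfg: SolverConfig, suffix: str = "") -> None:
    """Old-time right-hand sides of the CN system on one level.

    R_phi_i = phi_i/theta + (1/2) div(M_i grad mu) - div(phi_i u_alpha)
              + S_i   (everything at the old time level)
    R_mu_T  = -eps_TE^2 lap(phi_E_old)
    R_mu_E  = -eps_TE^2 lap(phi_T_old) [+ dW/dphi_E at the old time]

    Also freezes the mobilities M_i = Mbar phi_i^old used on both sides of
    the CN average.  ``suffix`` selects which stored copy holds the old-time
    fields (e.g. ``"__old"`` on freshly regridded blocks).
    """
    lev = h.level(kappa)
    th = cfg.theta
    for b in lev.blocks:
        f = b.data
        for nm, phi in (("Mob_V", "phi_V"), ("Mob_D", "phi_D"),
                        ("Mob_E", "phi_E")):
            f[nm] = prm.Mbar * f[phi + suffix].copy()
        need = [f"rhs_{u}" for u in TumorSystem.unknowns]
        b.alloc(need)
        ua = b.face_data["u_alpha"]
        phiT_pad = f["phi_V" + suffix] + f["phi_D" + suffix]
        lapT = st.laplacian(phiT_pad, lev.eta)
        lapE = st.laplacian(f["phi_E" + suffix], lev.eta)
        for phi, mob, mu, S in (("phi_V", "Mob_V", "mu_T", "S_V"),
                                ("phi_D", "Mob_D", "mu_T", "S_D"),
                                ("phi_E", "Mob_E", "mu_E", "S_E")):
            adv = st.upwind_div(f[phi + suffix], ua, lev.eta)
            diff = st.div_mobility_grad(f[mob], f[mu + suffix], lev.eta)
            b.interior(f"rhs_{phi}")[...] = (st.interior(f[phi + suffix]) / th
                                             + 0.5 * diff - adv
                                             + st.interior(f[S]))
        b.interior("rhs_mu_T")[...] = -prm.eps_TE**2 * lapE
        rhs_me = -prm.eps_TE**2 * lapT
        if prm.eps_e != 0.0:
            from .elastic import elastic_derivative
            rhs_me = rhs_me + elastic_derivative(b, prm, lev.eta)
        b.interior("rhs_mu_E")[...] = rhs_me


# ---------------------------------------------------------------------------
# smoothing / cycles / FMG
# ---------------------------------------------------------------------------

def smooth(h: MeshHierarchy, system: DiscreteSystem, kappa: int, nu: int,
           cfg: SolverConfig) -> None:
    """``nu`` red-black sweeps (ghosts refreshed between sweeps) plus
    ``nu_b`` extra sweeps on cells within ``d_kappa`` of block boundaries."""
    bcs = system.bc_map()
    for _ in range(nu):
        system.relax_once(h, kappa)
        tr.fill_level_ghosts(h, kappa, bcs)
    d = cfg.d_kappa(h, kappa)
    if cfg.nu_b > 0 and d > 0:
        for _ in range(cfg.nu_b):
            system.relax_once(h, kappa, band=d)
            tr.fill_level_ghosts(h, kappa, bcs)


def residual_norm(h: MeshHierarchy, system: DiscreteSystem, kappa: int,
                  exclude_covered: bool = False) -> float:
    """Scaled discrete l2 norm sqrt(sum r^2 / #cells) of R - L(psi) over the
    interior cells of one level (optionally excluding cells covered by the
    next finer level, so that composite norms count the finest data only)."""
    lev = h.level(kappa)
    total = 0.0
    count = 0
    cover = None
    if exclude_covered and kappa < h.kappa_max and h.level(kappa + 1).blocks:
        cover = [tr.coarse_box(fb) for fb in h.level(kappa + 1).blocks]
    for b in lev.blocks:
        res = system.residuals(h, kappa, b)
        w = np.ones(b.shape, dtype=bool)
        if cover:
            for clo, chi in cover:
                olo = [max(a, c) for a, c in zip(clo, b.lo)]
                ohi = [min(a, c) for a, c in zip(chi, b.hi)]
                if any(a > c for a, c in zip(olo, ohi)):
                    continue
                sl = tuple(slice(a - l, c - l + 1)
                           for a, c, l in zip(olo, ohi, b.lo))
                w[sl] = False
        for u in system.unknowns:
            total += float((res[u][w] ** 2).sum())
        count += int(w.sum()) * len(system.unknowns)
    return np.sqrt(total / count) if count else 0.0


def adapfas_cycle(h: MeshHierarchy, system: DiscreteSystem, kappa: int,
                  cfg: SolverConfig) -> None:
    """One recursive adaptive FAS cycle starting at level ``kappa``.

    Pre-smooth; restrict the iterate onto the coarse overlap; build the
    tau-corrected coarse right-hand side R[R_k - L_k(psi)] + L_{k-1}(R psi)
    on the overlap (the coarse level keeps its own RHS elsewhere); solve the
    coarse equation (nu0 smoothing at the coarsest level, else gamma
    recursive cycles); prolong the coarse correction, add, and post-smooth.
    Ghost layers are refreshed after every correction.
    """
    if kappa < h.kappa_min:
        raise ValueError("recursion below the coarsest level")
    bcs = system.bc_map()
    if kappa == h.kappa_min:
        smooth(h, system, kappa, cfg.nu1 + cfg.nu2, cfg)
        return

    smooth(h, system, kappa, cfg.nu1, cfg)

    coarse = h.level(kappa - 1)
    fine = h.level(kappa)
    unknowns = system.unknowns

    # save the coarse level's own RHS
    for cb in coarse.blocks:
        for u in unknowns:
            cb.data[f"savR_{u}"] = cb.data[f"rhs_{u}"].copy()

    # fine residuals before transfer
    fine_res = {id(b): system.residuals(h, kappa, b) for b in fine.blocks}

    # restrict iterate onto the overlap, update coarse ghosts; the result is
    # the reference iterate psi^0 that the coarse correction is measured from
    tr.restrict_level_to_coarse(h, kappa, unknowns)
    tr.fill_level_ghosts(h, kappa - 1, bcs)
    for cb in coarse.blocks:
        for u in unknowns:
            cb.data[f"sav0_{u}"] = cb.data[u].copy()

    # tau-corrected coarse RHS on the overlap
    for cb in coarse.blocks:
        Lc = system.apply_operator(h, kappa - 1, cb)
        for u in unknowns:
            cb.data[f"_Lc_{u}"] = Lc[u]
    for b in fine.blocks:
        clo, chi = tr.coarse_box(b)
        for u in unknowns:
            Rres = tr.restrict_avg(fine_res[id(b)][u])
            for cb in coarse.blocks:
                olo = [max(a, c) for a, c in zip(clo, cb.lo)]
                ohi = [min(a, c) for a, c in zip(chi, cb.hi)]
                if any(a > c for a, c in zip(olo, ohi)):
                    continue
                src = tuple(slice(a - l, c - l + 1)
                            for a, c, l in zip(olo, ohi, clo))
                dsti = tuple(slice(a - l, c - l + 1)
                             for a, c, l in zip(olo, ohi, cb.lo))
                dstp = tuple(slice(a - l + 1, c - l + 2)
                             for a, c, l in zip(olo, ohi, cb.lo))
                cb.data[f"rhs_{u}"][dstp] = (Rres[src]
                                             + cb.data[f"_Lc_{u}"][dsti])

    # coarse solve
    if kappa - 1 == h.kappa_min:
        smooth(h, system, kappa - 1, cfg.nu0, cfg)
    else:
        for _ in range(cfg.gamma):
            adapfas_cycle(h, system, kappa - 1, cfg)

    # correction (padded difference -> ghosts carry the homogeneous BCs)
    for cb in coarse.blocks:
        for u in unknowns:
            cb.data[f"corr_{u}"] = cb.data[u] - cb.data[f"sav0_{u}"]
    for u in unknowns:
        tr.prolong_correction_to_level(h, kappa, f"corr_{u}", u, add=True)
    tr.fill_level_ghosts(h, kappa, bcs)

    smooth(h, system, kappa, cfg.nu2, cfg)

    # restore the coarse level's own RHS; drop scratch
    for cb in coarse.blocks:
        for u in unknowns:
            cb.data[f"rhs_{u}"] = cb.data[f"savR_{u}"]
            for tag in ("sav0_", "savR_", "corr_", "_Lc_"):
                cb.data.pop(f"{tag}{u}", None)


def fmg_solve(h: MeshHierarchy, system: DiscreteSystem, cfg: SolverConfig,
              regrid_hook=None, log: list | None = None,
              time_step: int = 0) -> None:
    """Full multigrid over the hierarchy, optionally growing it.

    Nested iteration from the coarsest global level: nu0 smoothing at the
    bottom, ``r_kappa`` cycles per level below the root, then cycling to the
    per-level tolerance on levels >= 0.  After a level kappa >= 0 converges,
    ``regrid_hook(kappa)`` may create/replace level kappa+1 (flag + cluster
    + regrid); cubic FMG interpolation of the converged solution seeds the
    finer level's iterate.
    """
    bcs = system.bc_map()
    kmax = h.kappa_max
    for kappa in h.kappas():
        lev = h.level(kappa)
        if not lev.blocks:
            break
        tr.fill_level_ghosts(h, kappa, bcs)
        if kappa == h.kappa_min:
            smooth(h, system, kappa, cfg.nu0, cfg)
        elif kappa < 0:
            for _ in range(cfg.r_kappa):
                adapfas_cycle(h, system, kappa, cfg)
        else:
            tol = cfg.tol_level(kappa, kmax)
            it = 0
            res = residual_norm(h, system, kappa)
            while res > tol:
                if it >= cfg.max_outer_cycles:
                    raise SolverAbort(
                        f"level {kappa}: residual {res:.3e} > tol {tol:.3e} "
                        f"after {it} cycles",
                        residuals={kappa: res})
                adapfas_cycle(h, system, kappa, cfg)
                it += 1
                res = residual_norm(h, system, kappa)
                if log is not None:
                    from .mesh import count_dof
                    log.append({"time_step": time_step, "level": kappa,
                                "cycle": it, "residual": res,
                                "dof": count_dof(h)})

        # seed the next finer level
        if kappa < kmax:
            if kappa >= 0 and regrid_hook is not None:
                created = regrid_hook(kappa)
                if not created:
                    break
            if not h.level(kappa + 1).blocks:
                break
            tr.fill_level_ghosts(h, kappa, bcs)
            tr.fmg_interp_to_level(h, kappa + 1, system.unknowns)
            tr.fill_level_ghosts(h, kappa + 1, bcs)


def solve_scalar(h: MeshHierarchy, system: ScalarLinearSystem,
                 cfg: SolverConfig, tol: float | None = None,
                 max_cycles: int | None = None) -> float:
    """Iterate adaptive V-cycles from the finest active level until every
    level's residual norm is below ``tol``; returns the final worst norm."""
    tol = cfg.tol_min if tol is None else tol
    max_cycles = cfg.max_outer_cycles if max_cycles is None else max_cycles
    bcs = system.bc_map()
    active = [k for k in h.kappas() if h.level(k).blocks]
    for k in active:
        tr.fill_level_ghosts(h, k, bcs)
    top = active[-1]
    res = max(residual_norm(h, system, k, exclude_covered=True)
              for k in active)
    it = 0
    while res > tol:
        if it >= max_cycles:
            raise SolverAbort(
                f"scalar solve ({system.unknowns[0]}): residual {res:.3e} "
                f"> tol {tol:.3e} after {it} cycles")
        adapfas_cycle(h, system, top, cfg)
        it += 1
        res = max(residual_norm(h, system, k, exclude_covered=True)
                  for k in active)
    return res
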