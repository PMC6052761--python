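"""Right-hand sides, potentials, fluxes, sources, and boundary conditions of
the multispecies desmoplastic tumor model.

The model tracks normalized volume fractions of viable tumor cells (phi_V),
dead tumor cells (phi_D), extracellular matrix (phi_E), and healthy host
cells (phi_H = 1 - phi_V - phi_D - phi_E).  Cell and ECM species move with a
Darcy-type velocity and by Fickian fluxes of chemical potentials derived
from a ternary bulk free energy with square-gradient interface terms and an
optional ECM elastic energy.  Diffusible species (O2, glucose, CO2, ions,
growth and angiogenic factors) are quasi-steady reaction-diffusion fields;
matrix-degrading enzymes, myofibroblasts, and continuum blood/lymphatic
vessel densities evolve in time with advective, chemotactic, and haptotactic
fluxes.

Functions here are pointwise/stencil evaluations on block arrays; the
elliptic solves (pressure, quasi-steady species) reuse the multigrid
machinery of :mod:`tumormg.solver`.
"""

from __future__ import annotations

import numpy as np

from . import stencil as st
from . import transfer as tr
from .mesh import MeshHierarchy
from .params import ModelParams

__all__ = [
    "Q3",
    "heaviside",
    "effective_coefficient",
    "bulk_energy_derivatives",
    "bulk_energy_hessian",
    "chemical_potentials",
    "source_terms",
    "apply_bcs",
    "bc_table",
    "pressure_velocity_solve",
    "quasi_steady_species_system",
    "transient_species_rhs",
    "sprout_fraction_field",
    "phi_T_of",
    "phi_H_of",
]

# fields evolved/solved in the reduced ("lite") profile
LITE_FIELDS = ["phi_V", "phi_D", "phi_E", "mu_T", "mu_E", "p",
               "n", "g", "tgf", "taf", "m", "F_E", "B_nE", "L_nE"]
ION_FIELDS = ["w", "l", "b", "a", "s", "r"]
FULL_FIELDS = LITE_FIELDS + ION_FIELDS + ["q"]


def Q3(x):
    """Smooth interpolation function with Q3(0)=0, Q3(1)=1 (clamped)."""
    xc = np.clip(x, 0.0, 1.0)
    return xc * xc * (3.0 - 2.0 * xc)


def heaviside(x):
    """Sharp Heaviside with H(0) = 1."""
    return np.where(np.asarray(x) >= 0.0, 1.0, 0.0)


def phi_T_of(b):
    return b["phi_V"] + b["phi_D"]


def phi_H_of(b):
    return 1.0 - b["phi_V"] - b["phi_D"] - b["phi_E"]


def effective_coefficient(phi_T, phi_E, psi_E, psi_T, psi_H,
                          phi_H=None, eps=1e-12):
    """Tissue-effective coefficient blend.

    psi = psi_E Q3(phi_E) + [1 - Q3(phi_E)] {psi_T Q3(phi_T/phi_C)
          + psi_H [1 - Q3(phi_T/phi_C)]},  phi_C = phi_T + phi_H.

    Where the total cell fraction phi_C vanishes the inner blend degenerates
    to psi_H.
    """
    if phi_H is None:
        phi_H = 1.0 - phi_T - phi_E
    phi_C = phi_T + phi_H
    ratio = np.where(np.abs(phi_C) > eps, phi_T / np.where(
        np.abs(phi_C) > eps, phi_C, 1.0), 0.0)
    qE = Q3(phi_E)
    qr = Q3(ratio)
    return psi_E * qE + (1.0 - qE) * (psi_T * qr + psi_H * (1.0 - qr))


# ---------------------------------------------------------------------------
# bulk free energy
# ---------------------------------------------------------------------------

def bulk_energy_derivatives(phi_T, phi_E, p: ModelParams):
    """Pointwise (dF_b/dphi_T, dF_b/dphi_E) of the ternary bulk energy."""
    A1, A2, A3, A4, A5 = p.A1, p.A2, p.A3, p.A4, p.A5
    one = 1.0 - phi_T - phi_E
    dT = (2.0 * A1 * phi_T * one * (1.0 - 2.0 * phi_T - phi_E)
          + (A5 - A3) * (2.0 * phi_E - A5 - A3))
    dE = (2.0 * (phi_T + A2) * (phi_E - A3)
          - 2.0 * A1 * phi_T**2 * one
          + (phi_E - A5) * (2.0 * (1.0 - phi_T + A4) - 3.0 * phi_E + A5))
    return dT, dE


def bulk_energy_hessian(phi_T, phi_E, p: ModelParams):
    """Pointwise second derivatives (d2F/dT2, d2F/dTdE, d2F/dEdT, d2F/dE2)
    of the bulk energy (used by the pointwise Newton smoother)."""
    A1, A2 = p.A1, p.A2
    A3, A5 = p.A3, p.A5
    one = 1.0 - phi_T - phi_E
    two = 1.0 - 2.0 * phi_T - phi_E
    dTT = 2.0 * A1 * (one * two - phi_T * two - 2.0 * phi_T * one)
    dTE = 2.0 * A1 * phi_T * (-two - one) + 2.0 * (A5 - A3)
    dET = (2.0 * (phi_E - A3)
           - 2.0 * A1 * (2.0 * phi_T * one - phi_T**2)
           - 2.0 * (phi_E - A5))
    dEE = (2.0 * (phi_T + A2) + 2.0 * A1 * phi_T**2
           + (2.0 * (1.0 - phi_T + p.A4) - 3.0 * phi_E + A5)
           - 3.0 * (phi_E - A5))
    return dTT, dTE, dET, dEE


def chemical_potentials(h: MeshHierarchy, kappa: int, p: ModelParams,
                        dW_dphiE=None) -> None:
    """Evaluate mu_T and mu_E on every block of a level (ghosts of the phi
    fields must be current)::

        mu_T = dF_b/dphi_T - eps_T^2 lap(phi_T) - eps_TE^2 lap(phi_E)
        mu_E = dF_b/dphi_E + dW/dphi_E - eps_E^2 lap(phi_E)
               - eps_TE^2 lap(phi_T)
    """
    lev = h.level(kappa)
    for b in lev.blocks:
        phiT = b.data["phi_V"] + b.data["phi_D"]
        phiE = b.data["phi_E"]
        dT, dE = bulk_energy_derivatives(st.interior(phiT),
                                         st.interior(phiE), p)
        lapT = st.laplacian(phiT, lev.eta)
        lapE = st.laplacian(phiE, lev.eta)
        b.interior("mu_T")[...] = dT - p.eps_T**2 * lapT - p.eps_TE**2 * lapE
        muE = dE - p.eps_E**2 * lapE - p.eps_TE**2 * lapT
        if dW_dphiE is not None:
            muE = muE + dW_dphiE(b)
        elif p.eps_e != 0.0:
            from .elastic import elastic_derivative
            muE = muE + elastic_derivative(b, p)
        b.interior("mu_E")[...] = muE


# ---------------------------------------------------------------------------
# sources
# ---------------------------------------------------------------------------

def source_terms(fields: dict, f_sp, prm: ModelParams) -> dict:
    """Pointwise source terms for cells, ECM, MDEs, myofibroblasts, vessels.

    ``fields`` is a dict of co-located arrays (keys: n, g, tgf, taf, m,
    F_E, phi_V, phi_D, phi_E, B_nE, L_nE, p); ``f_sp`` is the regional
    sprouting-fraction field.

    The viable-cell source gates mitosis on oxygen above the hypoxic level
    (upregulated by tumor growth factors) and switches to necrosis below the
    oxygen/glucose viability limits; dead cells accumulate necrosed viable
    cells and lyse; ECM is secreted by myofibroblasts (adjustment factor
    ``A_F,E``) and degraded by MDEs.  The MDE, myofibroblast, and vessel
    sources are documented placeholder closures for the supplementary
    parameterization (production by viable cells / logistic sprouting /
    pressure crushing).
    """
    n, g, tgf, taf = fields["n"], fields["g"], fields["tgf"], fields["taf"]
    m, F_E = fields["m"], fields["F_E"]
    phi_V, phi_D, phi_E = fields["phi_V"], fields["phi_D"], fields["phi_E"]
    B, L = fields["B_nE"], fields["L_nE"]
    phi_T = phi_V + phi_D

    Hn = heaviside(n - prm.n_h)
    viable = heaviside(n - prm.n_vV) * heaviside(g - prm.g_vV)
    S_V = (prm.lam_MV * n * (1.0 + tgf) * Hn
           - prm.lam_NV * (1.0 - viable)) * phi_V
    S_D = prm.lam_NV * (1.0 - viable) * phi_V - prm.lam_LD * phi_D

    host_room = 1.0 - phi_T - phi_E
    hypox = 1.0 + prm.F_nEF * (prm.n_h - n) / (prm.n_h - prm.n_vF) \
        * heaviside(prm.n_h - n)
    A_FE = (host_room * (1.0 + tgf) * hypox
            * heaviside(n - prm.n_vF) * heaviside(tgf - prm.tgf_FE)
            * heaviside(host_room))
    F_tissue = F_E * phi_E
    S_E = prm.lam_FE * A_FE * F_tissue - prm.lam_deE * m * phi_E

    S_m = prm.lam_pro_m * phi_V - prm.lam_de_m * m
    S_FE = (prm.lam_pro_F * (1.0 + tgf) * heaviside(n - prm.n_vF)
            - prm.lam_apo_F
            - prm.lam_N_F * (1.0 - heaviside(n - prm.n_vF))) * F_E
    p_pos = np.maximum(fields["p"], 0.0)
    S_BnE = (prm.lam_sp_B * f_sp * taf * B * (1.0 - B)
             - prm.lam_cr_B * p_pos * B)
    S_LnE = (prm.lam_sp_L * f_sp * taf * L * (1.0 - L)
             - prm.lam_cr_L * p_pos * L)
    return {"S_V": S_V, "S_D": S_D, "S_E": S_E, "S_m": S_m, "S_FE": S_FE,
            "S_BnE": S_BnE, "S_LnE": S_LnE}


def sprout_fraction_field(h: MeshHierarchy, kappa: int, block,
                          prm: ModelParams) -> np.ndarray:
    """Octant-constant sprouting-fraction map (interior shape).

    The fraction of vessels that may sprout differs by domain octant
    (values ``sprout_fractions``), slightly perturbing the symmetry of
    vascular remodeling.
    """
    lev = h.level(kappa)
    nd = h.ndim
    axes = []
    for a in range(nd):
        L, R = h.domain[a]
        i = np.arange(block.lo[a], block.hi[a] + 1, dtype=float)
        x = L + (i - 0.5) * lev.eta
        axes.append((x > 0.5 * (L + R)).astype(int))
    grids = np.meshgrid(*axes, indexing="ij")
    octant = np.zeros(block.shape, dtype=int)
    for a, gbit in enumerate(grids):
        octant += gbit << a
    fr = np.asarray(prm.sprout_fractions, dtype=float)
    return fr[octant % len(fr)]


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------

def bc_table(prm: ModelParams) -> dict:
    """Physical boundary conditions for every model field.

    Zero-Neumann for the cell/ECM fractions and myofibroblasts; homogeneous
    Dirichlet for pressures, chemical potentials, waste/ion/growth-factor
    concentrations; Dirichlet 1 for oxygen and glucose; far-field Dirichlet
    for the vessel densities.
    """
    t = {}
    for name in ("phi_V", "phi_D", "phi_E", "F_E"):
        t[name] = ("neumann", None)
    for name in ("p", "q", "mu_T", "mu_E", "w", "l", "b", "a", "s", "r",
                 "tgf", "taf", "m"):
        t[name] = ("dirichlet", 0.0)
    t["n"] = ("dirichlet", 1.0)
    t["g"] = ("dirichlet", 1.0)
    t["B_nE"] = ("dirichlet", prm.B_inf)
    t["L_nE"] = ("dirichlet", prm.L_inf)
    return t


def apply_bcs(h: MeshHierarchy, kappa: int, prm: ModelParams,
              names=None) -> None:
    """Fill physical-boundary ghosts per the model's boundary conditions."""
    table = bc_table(prm)
    if names is not None:
        table = {k: v for k, v in table.items() if k in names}
    tr.apply_physical_bcs(h, kappa, table)


# ---------------------------------------------------------------------------
# pressure / velocities
# ---------------------------------------------------------------------------

def _forcing_faces(b, eta, prm: ModelParams, suffix: str = ""):
    """Face values of G = gamma_T eps_T mu_T grad(phi_T)
    + gamma_E eps_E mu_E grad(phi_E)."""
    phiT = b.data["phi_V" + suffix] + b.data["phi_D" + suffix]
    phiE = b.data["phi_E" + suffix]
    muT = b.data["mu_T" + suffix]
    muE = b.data["mu_E" + suffix]
    out = []
    for a in range(phiT.ndim):
        G = (prm.gamma_T * prm.eps_T * st.face_avg(muT, a)
             * st.face_diff(phiT, a) / eta
             + prm.gamma_E * prm.eps_E * st.face_avg(muE, a)
             * st.face_diff(phiE, a) / eta)
        out.append(G)
    return out


def pressure_velocity_solve(h: MeshHierarchy, prm: ModelParams, cfg,
                            with_q: bool = False, tol: float = None) -> None:
    """Solve the cell-ECM phase pressure (and optionally the interstitial
    pressure), then evaluate face velocities u_alpha, u_beta, u_E.

    The pressure solves the variable-coefficient elliptic equation
    ``div[k_alpha (grad p - G)] = -(S_V + S_D + S_E)`` with ``p = 0`` on the
    boundary; velocities follow from the same face fluxes, and the ECM
    velocity adds the Fickian drift ``-M~ grad(mu_E)`` with ``M~ = Mbar
    phi_E``.  Requires mu/phi ghosts and sources ("S_total") to be current
    on every active level.
    """
    from .solver import ScalarLinearSystem, solve_scalar

    sysP = ScalarLinearSystem("p", ("dirichlet", 0.0))
    for kappa in h.kappas():
        lev = h.level(kappa)
        for b in lev.blocks:
            if "p" not in b.data:
                b.alloc(["p"])
            b.alloc(["coef_a_p", "coef_d_p", "rhs_p"])
            b.data["coef_d_p"][...] = prm.k_alpha
            G = _forcing_faces(b, lev.eta, prm)
            kG = [prm.k_alpha * g for g in G]
            b.interior("rhs_p")[...] = (st.interior(b.data["S_total"])
                                        + st.div_face_flux(kG, lev.eta))
    solve_scalar(h, sysP, cfg, tol=tol)

    for kappa in h.kappas():
        compute_face_velocities(h, kappa, prm)

    if with_q:
        sysQ = ScalarLinearSystem("q", ("dirichlet", 0.0))
        for kappa in h.kappas():
            lev = h.level(kappa)
            for b in lev.blocks:
                if "q" not in b.data:
                    b.alloc(["q"])
                b.alloc(["coef_a_q", "coef_d_q", "rhs_q"])
                b.data["coef_d_q"][...] = 1.0
                b.interior("rhs_q")[...] = (-prm.R_alphabeta / prm.k_beta
                                            * st.interior(b.data["S_total"]))
        solve_scalar(h, sysQ, cfg, tol=tol)
        for kappa in h.kappas():
            lev = h.level(kappa)
            for b in lev.blocks:
                b.face_data["u_beta"] = tuple(
                    -prm.k_beta * st.face_diff(b.data["q"], a) / lev.eta
                    for a in range(h.ndim))


def compute_face_velocities(h: MeshHierarchy, kappa: int, prm: ModelParams,
                            suffix: str = "") -> None:
    """Darcy and ECM face velocities from (p, mu, phi) fields on one level:
    u_alpha = -k_alpha (grad p - G) and u_E = u_alpha - M~ grad mu_E with
    M~ = Mbar phi_E.  ``suffix`` selects the stored field copy."""
    lev = h.level(kappa)
    for b in lev.blocks:
        G = _forcing_faces(b, lev.eta, prm, suffix)
        u_alpha = []
        for a in range(h.ndim):
            u_alpha.append(-prm.k_alpha
                           * (st.face_diff(b.data["p" + suffix], a) / lev.eta
                              - G[a]))
        b.face_data["u_alpha"] = tuple(u_alpha)
        phiE = b.data["phi_E" + suffix]
        muE = b.data["mu_E" + suffix]
        u_E = []
        for a in range(h.ndim):
            Mt = prm.Mbar * st.face_avg(phiE, a)
            u_E.append(u_alpha[a] - Mt * st.face_diff(muE, a) / lev.eta)
        b.face_data["u_E"] = tuple(u_E)


# ---------------------------------------------------------------------------
# quasi-steady diffusible species
# ---------------------------------------------------------------------------

def _setup_linear_species(h, name, prm, a_fn, d_fn, rhs_fn):
    """Populate coef/rhs arrays for one quasi-steady species on all levels.

    ``a_fn/d_fn/rhs_fn(block_fields) -> array`` give the reaction
    coefficient, diffusivity, and right-hand side from co-located (padded)
    field arrays.
    """
    for kappa in h.kappas():
        for b in h.level(kappa).blocks:
            if name not in b.data:
                b.alloc([name])
            b.alloc([f"coef_a_{name}", f"coef_d_{name}", f"rhs_{name}"])
            f = b.data
            b.data[f"coef_a_{name}"][...] = a_fn(f)
            b.data[f"coef_d_{name}"][...] = d_fn(f)
            b.data[f"rhs_{name}"][...] = rhs_fn(f)


def quasi_steady_species_system(h: MeshHierarchy, prm: ModelParams, cfg,
                                with_ions: bool = False, tol: float = None,
                                picard_iters: int = 6) -> None:
    """Solve the quasi-steady diffusible species to steady state.

    Oxygen, glucose, and the tumorigenic factors are linear
    reaction-diffusion problems; the charged species (lactate, bicarbonate,
    H+, Na+) share an electro-diffusive drift and are iterated with a
    Picard linearization, with Cl- closing the system by electroneutrality.
    Supply terms are ``(vessel density in tissue) x (unit vascular
    concentration)``: n_C = B_nE phi_E etc., so supply vanishes without
    vessels.
    """
    from .solver import ScalarLinearSystem, solve_scalar

    def eff(f, triple):
        phiT = f["phi_V"] + f["phi_D"]
        return effective_coefficient(phiT, f["phi_E"], *triple,
                                     phi_H=1.0 - phiT - f["phi_E"],
                                     eps=prm.phiC_eps)

    def vessel_supply(f):
        return f["B_nE"] * f["phi_E"]

    # oxygen: div(D grad n) + k_n1 n_C - (k_n1 + k_n2) n = 0
    _setup_linear_species(
        h, "n", prm,
        a_fn=lambda f: eff(f, prm.lam_B_n) + eff(f, prm.k_n2),
        d_fn=lambda f: eff(f, prm.D_n),
        rhs_fn=lambda f: eff(f, prm.lam_B_n) * vessel_supply(f))
    solve_scalar(h, ScalarLinearSystem("n", ("dirichlet", 1.0)), cfg, tol=tol)

    _setup_linear_species(
        h, "g", prm,
        a_fn=lambda f: eff(f, prm.lam_B_g) + eff(f, prm.k_g2),
        d_fn=lambda f: eff(f, prm.D_g),
        rhs_fn=lambda f: eff(f, prm.lam_B_g) * vessel_supply(f))
    solve_scalar(h, ScalarLinearSystem("g", ("dirichlet", 1.0)), cfg, tol=tol)

    # tumor growth factor: production by viable cells, decay/uptake
    _setup_linear_species(
        h, "tgf", prm,
        a_fn=lambda f: (prm.lam_pro_tgf * f["phi_V"] + prm.lam_de_tgf
                        + prm.lam_U_tgf),
        d_fn=lambda f: eff(f, prm.D_tgf),
        rhs_fn=lambda f: prm.lam_pro_tgf * f["phi_V"])
    solve_scalar(h, ScalarLinearSystem("tgf", ("dirichlet", 0.0)), cfg,
                 tol=tol)

    # tumor angiogenic factor: uptake by proliferating vessels
    _setup_linear_species(
        h, "taf", prm,
        a_fn=lambda f: (prm.lam_pro_taf * f["phi_V"] + prm.lam_de_taf
                        + prm.lam_U_taf * f["B_nE"] * f["phi_E"]),
        d_fn=lambda f: eff(f, prm.D_taf),
        rhs_fn=lambda f: prm.lam_pro_taf * f["phi_V"])
    solve_scalar(h, ScalarLinearSystem("taf", ("dirichlet", 0.0)), cfg,
                 tol=tol)

    if with_ions:
        _solve_ion_system(h, prm, cfg, tol, picard_iters, eff, vessel_supply)


def _solve_ion_system(h, prm, cfg, tol, picard_iters, eff, vessel_supply):
    """CO2 + charged species (l, b, a, s) with shared electro-diffusive
    drift, Picard-linearized; r (Cl-) closes by electroneutrality."""
    from .solver import ScalarLinearSystem, solve_scalar

    ions = [("l", prm.z_l, prm.D_l), ("b", prm.z_b, prm.D_b),
            ("a", prm.z_a, prm.D_a), ("s", prm.z_s, prm.D_s)]
    for _ in range(picard_iters):
        # CO2: + k_n2 n + k_r b a + k_w w_C - (k_f + k_w) w = 0
        _setup_linear_species(
            h, "w", prm,
            a_fn=lambda f: prm.k_f + eff(f, prm.lam_B_w),
            d_fn=lambda f: eff(f, prm.D_w),
            rhs_fn=lambda f: (eff(f, prm.k_n2) * f["n"]
                              + prm.k_r * f["b"] * f["a"]
                              + eff(f, prm.lam_B_w) * vessel_supply(f)))
        solve_scalar(h, ScalarLinearSystem("w", ("dirichlet", 0.0)), cfg,
                     tol=tol)

        # shared drift vector at faces, from the previous iterate
        drift = {}
        for kappa in h.kappas():
            lev = h.level(kappa)
            for blk in lev.blocks:
                f = blk.data
                num = []
                for a in range(h.ndim):
                    acc = 0.0
                    for nm, z, trp in ions + [("r", prm.z_r, prm.D_l)]:
                        D = eff(f, trp)
                        acc = acc + z * st.face_avg(D, a) \
                            * st.face_diff(f[nm], a) / lev.eta
                    num.append(acc)
                den = 0.0
                for nm, z, trp in ions + [("r", prm.z_r, prm.D_l)]:
                    den = den + z**2 * eff(f, trp) * f[nm]
                drift[(kappa, id(blk))] = (num, den)

        for nm, z, trp in ions:
            srcs = {
                "l": lambda f: (2 * prm.R_gn * eff(f, prm.k_g2) * f["g"]
                                - eff(f, prm.k_n2) * f["n"] / 3.0
                                + eff(f, prm.lam_B_l) * vessel_supply(f)),
                "b": lambda f: prm.k_f * f["w"],
                "a": lambda f: (2 * prm.R_gn * eff(f, prm.k_g2) * f["g"]
                                - eff(f, prm.k_n2) * f["n"] / 3.0
                                + prm.k_f * f["w"]
                                + eff(f, prm.lam_B_l) * vessel_supply(f)),
                "s": lambda f: np.zeros_like(f["n"]),
            }[nm]
            acoefs = {
                "l": lambda f: eff(f, prm.lam_B_l) + 0.0 * f["n"],
                "b": lambda f: prm.k_r * f["a"],
                "a": lambda f: prm.k_r * f["b"] + eff(f, prm.lam_B_l),
                "s": lambda f: np.zeros_like(f["n"]),
            }[nm]

            def rhs_fn(f, _src=srcs, _nm=nm, _z=z, _trp=trp):
                return _src(f)

            _setup_linear_species(h, nm, prm, a_fn=acoefs,
                                  d_fn=lambda f, _t=trp: eff(f, _t),
                                  rhs_fn=rhs_fn)
            # drift term: + div(D z c drift/den) moved to the RHS (Picard)
            for kappa in h.kappas():
                lev = h.level(kappa)
                for blk in lev.blocks:
                    f = blk.data
                    num, den = drift[(kappa, id(blk))]
                    D = eff(f, trp)
                    fluxes = []
                    for a in range(h.ndim):
                        den_f = st.face_avg(den, a)
                        den_f = np.where(np.abs(den_f) > prm.drift_eps,
                                         den_f, np.inf)
                        c_f = st.face_avg(f[nm], a)
                        fluxes.append(st.face_avg(D, a) * z * c_f
                                      * num[a] / den_f)
                    blk.interior(f"rhs_{nm}")[...] += st.div_face_flux(
                        fluxes, lev.eta)
            solve_scalar(h, ScalarLinearSystem(nm, ("dirichlet", 0.0)), cfg,
                         tol=tol)

        # electroneutrality closure for Cl-
        for kappa in h.kappas():
            for blk in h.level(kappa).blocks:
                f = blk.data
                blk.data["r"][...] = -(prm.z_l * f["l"] + prm.z_b * f["b"]
                                       + prm.z_a * f["a"] + prm.z_s * f["s"]
                                       ) / prm.z_r


# ---------------------------------------------------------------------------
# transient species (MDEs, myofibroblasts, vessels)
# ---------------------------------------------------------------------------

def transient_species_rhs(h: MeshHierarchy, kappa: int,
                          prm: ModelParams) -> dict:
    """Explicit advective/taxis flux divergences for F_E, B_nE, L_nE on one
    level (per block, interior-shaped arrays).

    Myofibroblasts advect with the ECM velocity and chemotax up the TGF
    gradient; vessel densities advect with u_E, chemotax up the angiogenic
    factor gradient, and haptotax up the ECM gradient (all upwinded); the
    vessels' Fickian diffusion is left to the implicit update.  Requires
    ``u_E`` face velocities and current ghosts of tgf, taf, phi_E.
    """
    lev = h.level(kappa)
    out = {}
    for b in lev.blocks:
        f = b.data
        uE = b.face_data["u_E"]
        gt = st.grad_faces(f["tgf"], lev.eta)
        ga = st.grad_faces(f["taf"], lev.eta)
        ge = st.grad_faces(f["phi_E"], lev.eta)
        vF = tuple(uE[a] + prm.D_F * gt[a] for a in range(h.ndim))
        vB = tuple(uE[a] + prm.chi_che_B * prm.A_che * ga[a]
                   + prm.chi_hap_B * prm.A_hap * ge[a]
                   for a in range(h.ndim))
        vL = tuple(uE[a] + prm.chi_che_L * prm.A_che * ga[a]
                   + prm.chi_hap_L * prm.A_hap * ge[a]
                   for a in range(h.ndim))
        out[id(b)] = {
            "F_E": -st.upwind_div(f["F_E"], vF, lev.eta),
            "B_nE": -st.upwind_div(f["B_nE"], vB, lev.eta),
            "L_nE": -st.upwind_div(f["L_nE"], vL, lev.eta),
        }
    return out
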