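"""ECM elastic energy: strain, stress, dW/dphi_E, and the displacement solve.

The ECM phase carries an elastic strain energy W with dilatational
eigenstrains for the ECM and cell phases and phase-interpolated Lame
constants.  The displacement field solves the mechanical equilibrium
``div T = 0`` with zero displacement on the external boundary; the energy's
variational derivative dW/dphi_E enters the ECM chemical potential.

Disabled by default (``eps_e = 0``): the Lame constants and eigenstrains are
supplement-only quantities, shipped here as documented placeholders.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.linalg import LinearOperator, gmres

from . import stencil as st
from .mesh import MeshHierarchy
from .params import ModelParams

__all__ = ["elastic_derivative", "solve_displacement", "elastic_state"]


def _strain(b, eta):
    """Cell-centered infinitesimal strain E_mn = (d_n u_m + d_m u_n)/2 from
    stored displacement components (zero if absent)."""
    nd = b.ndim
    shape = b.shape
    E = np.zeros((nd, nd) + shape)
    if "ud_0" not in b.data:
        return E
    for m in range(nd):
        u = b.data[f"ud_{m}"]
        for n_ in range(nd):
            lo = [slice(1, -1)] * nd
            hi = [slice(1, -1)] * nd
            lo[n_] = slice(0, -2)
            hi[n_] = slice(2, None)
            dmn = (u[tuple(hi)] - u[tuple(lo)]) / (2.0 * eta)
            E[m, n_] += 0.5 * dmn
            E[n_, m] += 0.5 * dmn
    return E


def elastic_state(b, prm: ModelParams, eta: float) -> dict:
    """Strain/stress bundle on one block (interior arrays).

    Returns E (strain), E_T (elastic strain E - E*), the eigenstrain
    interpolant Estar, the stress T, the stress jump Tstar, and the
    interpolated Lame constants L1, L2.
    """
    from .model import Q3

    nd = b.ndim
    phiE = st.interior(b.data["phi_E"])
    q = Q3(phiE)
    E = _strain(b, eta)
    estar_T = prm.Estar_E - prm.Estar_C           # (E_T*) diagonal value
    estar = q * estar_T + prm.Estar_C             # E* diagonal value
    L1 = q * (prm.L1E - prm.L1C) + prm.L1C
    L2 = q * (prm.L2E - prm.L2C) + prm.L2C
    ET = E.copy()
    for m in range(nd):
        ET[m, m] -= estar
    trET = sum(ET[m, m] for m in range(nd))
    T = np.zeros_like(E)
    Tstar = np.zeros_like(E)
    for m in range(nd):
        for n_ in range(nd):
            T[m, n_] = 2.0 * L2 * ET[m, n_]
            Tstar[m, n_] = 2.0 * (1.0 - prm.L2C) * ET[m, n_]
            if m == n_:
                T[m, n_] += L1 * trET
                Tstar[m, n_] += (prm.L1E - prm.L1C) * trET
    return {"E": E, "E_T": ET, "Estar": estar, "Estar_T": estar_T,
            "T": T, "Tstar": Tstar, "L1": L1, "L2": L2, "trET": trET}


def elastic_derivative(b, prm: ModelParams, eta: float = 1.0) -> np.ndarray:
    """dW/dphi_E = eps_e [6 phi_E (1-phi_E)]
    sum_ij [ (E_T)_ij T*_ij / 2 - (E_T*)_ij T_ij ]  (interior array).

    Vanishes identically at phi_E in {0, 1} through the prefactor.
    """
    nd = b.ndim
    phiE = st.interior(b.data["phi_E"])
    s = elastic_state(b, prm, eta)
    ET, T, Tstar = s["E_T"], s["T"], s["Tstar"]
    acc = np.zeros(b.shape)
    for m in range(nd):
        for n_ in range(nd):
            acc += 0.5 * ET[m, n_] * Tstar[m, n_]
            if m == n_:
                acc -= s["Estar_T"] * T[m, n_]
    return prm.eps_e * 6.0 * phiE * (1.0 - phiE) * acc


def solve_displacement(h: MeshHierarchy, prm: ModelParams, kappa: int = 0,
                       tol: float = 1e-10, maxiter: int = 2000) -> None:
    """Solve mechanical equilibrium div T = 0 for the displacement on the
    (single-block) level ``kappa`` with zero-displacement boundary.

    Conservative face-flux discretization of the variable-coefficient
    Lame operator; the eigenstress divergence forms the right-hand side.
    Solved matrix-free with GMRES (the system is small at desk scale).
    """
    if min(prm.L1E, prm.L2E, prm.L1C, prm.L2C) <= 0.0:
        raise ValueError("Lame constants must be positive")
    from .model import Q3

    lev = h.level(kappa)
    if len(lev.blocks) != 1:
        raise ValueError("displacement solve expects a single-block level")
    b = lev.blocks[0]
    nd = b.ndim
    eta = lev.eta
    shape = b.shape
    ncell = int(np.prod(shape))
    phiE = b.data["phi_E"]
    q = Q3(phiE)
    L1 = q * (prm.L1E - prm.L1C) + prm.L1C
    L2 = q * (prm.L2E - prm.L2C) + prm.L2C
    estar = q * (prm.Estar_E - prm.Estar_C) + prm.Estar_C

    def pad_dirichlet(ui):
        arr = np.zeros(tuple(n + 2 for n in shape))
        arr[(slice(1, -1),) * nd] = ui
        for a in range(nd):
            g0 = [slice(1, -1)] * nd
            i0 = [slice(1, -1)] * nd
            g0[a] = 0
            i0[a] = 1
            arr[tuple(g0)] = -arr[tuple(i0)]
            g0[a] = -1
            i0[a] = -2
            arr[tuple(g0)] = -arr[tuple(i0)]
        return arr

    def centered(arr, a):
        lo = [slice(1, -1)] * nd
        hi = [slice(1, -1)] * nd
        lo[a] = slice(0, -2)
        hi[a] = slice(2, None)
        return (arr[tuple(hi)] - arr[tuple(lo)]) / (2.0 * eta)

    def div_T(u_pads, include_eigen: bool):
        """Divergence of the stress for each component (interior arrays)."""
        cgrad = [[centered(u_pads[m], a) for a in range(nd)]
                 for m in range(nd)]
        out = []
        for i in range(nd):
            fluxes = []
            for j in range(nd):
                # face values along axis j
                dui_dj = st.face_diff(u_pads[i], j) / eta
                duj_di = _face_avg_of_interior(cgrad[j][i], u_pads, j, nd) \
                    if i != j else dui_dj
                Eij = 0.5 * (dui_dj + duj_di) if i != j else dui_dj
                L2f = st.face_avg(L2, j)
                F = 2.0 * L2f * Eij
                if i == j:
                    trE = dui_dj.copy()
                    for k in range(nd):
                        if k != j:
                            trE += _face_avg_of_interior(cgrad[k][k],
                                                         u_pads, j, nd)
                    F += st.face_avg(L1, j) * trE
                    if include_eigen:
                        ef = st.face_avg(estar, j)
                        F -= (2.0 * L2f + nd * st.face_avg(L1, j)) * ef
                fluxes.append(F)
            out.append(st.div_face_flux(fluxes, eta))
        return out

    def _face_avg_of_interior(cell_arr, u_pads, axis, nd_):
        pad = np.zeros(tuple(n + 2 for n in cell_arr.shape))
        pad[(slice(1, -1),) * nd_] = cell_arr
        for a in range(nd_):
            g0 = [slice(1, -1)] * nd_
            i0 = [slice(1, -1)] * nd_
            g0[a] = 0
            i0[a] = 1
            pad[tuple(g0)] = pad[tuple(i0)]
            g0[a] = -1
            i0[a] = -2
            pad[tuple(g0)] = pad[tuple(i0)]
        return st.face_avg(pad, axis)

    def matvec(x):
        us = [pad_dirichlet(x[k * ncell:(k + 1) * ncell].reshape(shape))
              for k in range(nd)]
        res = div_T(us, include_eigen=False)
        return np.concatenate([r.ravel() for r in res])

    rhs_parts = div_T([pad_dirichlet(np.zeros(shape)) for _ in range(nd)],
                      include_eigen=True)
    rhs = -np.concatenate([r.ravel() for r in rhs_parts])
    A = LinearOperator((nd * ncell, nd * ncell), matvec=matvec)
    x, info = gmres(A, rhs, rtol=tol, maxiter=maxiter)
    if info != 0:
        raise RuntimeError(f"displacement solve did not converge (info={info})")
    for k in range(nd):
        name = f"ud_{k}"
        if name not in b.data:
            b.alloc([name])
        b.interior(name)[...] = x[k * ncell:(k + 1) * ncell].reshape(shape)
        # Dirichlet ghosts
        arr = b.data[name]
        for a in range(nd):
            g0 = [slice(None)] * nd
            i0 = [slice(None)] * nd
            g0[a] = 0
            i0[a] = 1
            arr[tuple(g0)] = -arr[tuple(i0)]
            g0[a] = -1
            i0[a] = -2
            arr[tuple(g0)] = -arr[tuple(i0)]
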