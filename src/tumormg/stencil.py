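"""Finite-difference stencils on padded (one-ghost-layer) cell arrays.

All functions take arrays of shape ``interior + 2`` per axis and return
interior-shaped results unless noted.  Face arrays for axis ``a`` have the
interior shape with the ``a`` extent enlarged by one (faces ``i-1/2`` for
``i = lo .. hi+1``, both boundary faces included).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "interior",
    "neighbor_sum",
    "laplacian",
    "face_diff",
    "face_avg",
    "div_face_flux",
    "grad_faces",
    "upwind_div",
    "div_mobility_grad",
]


def _ax(arr, axis, sl):
    idx = [slice(1, -1)] * arr.ndim
    idx[axis] = sl
    return arr[tuple(idx)]


def interior(arr: np.ndarray) -> np.ndarray:
    return arr[(slice(1, -1),) * arr.ndim]


def neighbor_sum(arr: np.ndarray) -> np.ndarray:
    """Sum of the 2*ndim face neighbors of every interior cell."""
    out = np.zeros(tuple(n - 2 for n in arr.shape))
    for a in range(arr.ndim):
        out += _ax(arr, a, slice(2, None)) + _ax(arr, a, slice(0, -2))
    return out


def laplacian(arr: np.ndarray, eta: float) -> np.ndarray:
    """Standard 2*ndim+1-point Laplacian."""
    return (neighbor_sum(arr) - 2 * arr.ndim * interior(arr)) / eta**2


def face_diff(arr: np.ndarray, axis: int) -> np.ndarray:
    """Differences across axis-``axis`` faces: u[i] - u[i-1], including both
    boundary faces (uses the ghost layer)."""
    return _ax(arr, axis, slice(1, None)) - _ax(arr, axis, slice(0, -1))


def face_avg(arr: np.ndarray, axis: int) -> np.ndarray:
    """Arithmetic face average of a cell-centered quantity."""
    return 0.5 * (_ax(arr, axis, slice(1, None)) + _ax(arr, axis, slice(0, -1)))


def div_face_flux(fluxes, eta: float) -> np.ndarray:
    """Divergence of per-axis face fluxes: sum_a (F_{i+1/2} - F_{i-1/2})/eta."""
    nd = len(fluxes)
    out = None
    for a in range(nd):
        F = fluxes[a]
        hi = [slice(None)] * nd
        lo = [slice(None)] * nd
        hi[a] = slice(1, None)
        lo[a] = slice(0, -1)
        d = (F[tuple(hi)] - F[tuple(lo)]) / eta
        out = d if out is None else out + d
    return out


def grad_faces(arr: np.ndarray, eta: float):
    """Per-axis face gradients (u[i] - u[i-1]) / eta."""
    return tuple(face_diff(arr, a) / eta for a in range(arr.ndim))


def upwind_div(arr: np.ndarray, vel_faces, eta: float) -> np.ndarray:
    """First-order upwind discretization of div(u * v) with face velocities.

    ``arr`` is the padded transported quantity, ``vel_faces`` the per-axis
    face-velocity arrays.
    """
    nd = arr.ndim
    fluxes = []
    for a in range(nd):
        left = _ax(arr, a, slice(0, -1))
        right = _ax(arr, a, slice(1, None))
        v = vel_faces[a]
        fluxes.append(np.where(v > 0.0, left, right) * v)
    return div_face_flux(fluxes, eta)


def div_mobility_grad(mob: np.ndarray, u: np.ndarray, eta: float) -> np.ndarray:
    """div(M grad u) with face mobilities from arithmetic cell averages."""
    fluxes = []
    for a in range(u.ndim):
        fluxes.append(face_avg(mob, a) * face_diff(u, a) / eta)
    return div_face_flux(fluxes, eta)
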