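"""Inter-grid transfer operators for the block-structured hierarchy.

Four operator families move data between levels (refinement ratio fixed at 2,
cell-centered everywhere):

* ``restrict_avg`` — fine-to-coarse averaging over the 2^d children of each
  coarse cell (exact on linear fields).
* ``prolong_linear`` — bi/trilinear coarse-to-fine interpolation used for the
  coarse-grid correction; per fine child the tensor-product weights are the
  classical {9,3,3,1}/16 (2D) and {27,9,9,9,3,3,3,1}/64 (3D) combinations.
* ``fmg_interp_cubic`` — cubic Lagrange interpolation with 1D weights
  (-7, 105, 35, -5)/128 (and its mirror image), applied axis by axis; used
  for the full-multigrid initial guess and for populating newly refined
  blocks (exact on cubics).
* ``fill_ghost_quadratic`` — two-stage quadratic interpolation of coarse data
  onto fine-block ghost layers at coarse-fine interfaces: a tangential pass
  with weights (30, 5, -3)/32 onto intermediate points, then a normal-direction
  quadratic through the intermediate point and two interior fine cells; corner
  and edge ghosts interpolate along the inward diagonal.  Ghosts overlapping a
  same-level neighbor's interior are then overwritten by that neighbor's
  cell-centered data.

Interpolation near physical boundaries degrades gracefully: where a wide
stencil has no data (beyond the single ghost ring), missing values are filled
with the nearest available data, localising the order reduction to the
outermost cells.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt

from .mesh import Block, Level, MeshHierarchy

__all__ = [
    "restrict_avg",
    "prolong_linear",
    "fmg_interp_cubic",
    "fill_ghost_quadratic",
    "fill_level_ghosts",
    "apply_physical_bcs",
    "gather_patch",
    "scatter_to_level",
    "restrict_level_to_coarse",
    "prolong_correction_to_level",
    "fmg_interp_to_level",
    "exchange_same_level",
]

BC = tuple  # ("neumann", None) or ("dirichlet", value)


# ---------------------------------------------------------------------------
# low-level array operators
# ---------------------------------------------------------------------------

def restrict_avg(fine: np.ndarray) -> np.ndarray:
    """Coarsen by averaging 2^d children per coarse cell.

    ``fine`` is an interior-only array with even extents per axis.
    """
    for n in fine.shape:
        if n % 2:
            raise ValueError(f"restrict_avg needs even extents, got {fine.shape}")
    out = np.asarray(fine, dtype=np.float64)
    for a in range(out.ndim):
        s0 = [slice(None)] * out.ndim
        s1 = [slice(None)] * out.ndim
        s0[a] = slice(0, None, 2)
        s1[a] = slice(1, None, 2)
        out = 0.5 * (out[tuple(s0)] + out[tuple(s1)])
    return out


def _interleave(lo: np.ndarray, hi: np.ndarray, axis: int) -> np.ndarray:
    shp = list(lo.shape)
    shp[axis] *= 2
    out = np.empty(shp, dtype=np.float64)
    s0 = [slice(None)] * lo.ndim
    s1 = [slice(None)] * lo.ndim
    s0[axis] = slice(0, None, 2)
    s1[axis] = slice(1, None, 2)
    out[tuple(s0)] = lo
    out[tuple(s1)] = hi
    return out


def _axslice(arr: np.ndarray, axis: int, sl: slice) -> np.ndarray:
    idx = [slice(None)] * arr.ndim
    idx[axis] = sl
    return arr[tuple(idx)]


def _prolong_linear_axis(arr: np.ndarray, axis: int) -> np.ndarray:
    """One-axis linear refinement; consumes one ghost layer along ``axis``."""
    c = _axslice(arr, axis, slice(1, -1))
    m = _axslice(arr, axis, slice(0, -2))
    p = _axslice(arr, axis, slice(2, None))
    lo = 0.75 * c + 0.25 * m
    hi = 0.75 * c + 0.25 * p
    return _interleave(lo, hi, axis)


def prolong_linear(coarse: np.ndarray) -> np.ndarray:
    """Bi/trilinear coarse-to-fine interpolation.

    ``coarse`` must carry one ghost layer per face; the result covers the
    fine interior, shape ``2*(n-2)`` per axis.  Axes are processed x, y, z;
    the per-axis weights (3/4, 1/4) compose to the printed {27,9,3,1}/64
    (3D) and {9,3,3,1}/16 (2D) child formulas.
    """
    out = np.asarray(coarse, dtype=np.float64)
    for a in range(out.ndim):
        out = _prolong_linear_axis(out, a)
    return out


def _cubic_axis(arr: np.ndarray, axis: int) -> np.ndarray:
    """One-axis cubic Lagrange refinement; consumes two ghost layers."""
    jm2 = _axslice(arr, axis, slice(0, -4))
    jm1 = _axslice(arr, axis, slice(1, -3))
    j = _axslice(arr, axis, slice(2, -2))
    jp1 = _axslice(arr, axis, slice(3, -1))
    jp2 = _axslice(arr, axis, slice(4, None))
    lo = (-5.0 * jm2 + 35.0 * jm1 + 105.0 * j - 7.0 * jp1) / 128.0
    hi = (-7.0 * jm1 + 105.0 * j + 35.0 * jp1 - 5.0 * jp2) / 128.0
    return _interleave(lo, hi, axis)


def fmg_interp_cubic(coarse: np.ndarray) -> np.ndarray:
    """Cubic (bicubic/tricubic by tensor product) FMG interpolation.

    ``coarse`` must carry two ghost layers per face; the result covers the
    fine interior, shape ``2*(n-4)`` per axis.  The 1D weights are
    (-7, 105, 35, -5)/128 for the child offset +eta_f/2 from its parent and
    the mirror image (-5, 35, 105, -7)/128 for the other child.
    """
    out = np.asarray(coarse, dtype=np.float64)
    for a in range(out.ndim):
        out = _cubic_axis(out, a)
    return out


def _quad_tangential_axis(arr: np.ndarray, axis: int) -> np.ndarray:
    """One-axis quadratic interpolation of coarse data to fine tangential
    positions; weights (30, 5, -3)/32.  Consumes one ghost layer."""
    c = _axslice(arr, axis, slice(1, -1))
    m = _axslice(arr, axis, slice(0, -2))
    p = _axslice(arr, axis, slice(2, None))
    lo = (30.0 * c + 5.0 * m - 3.0 * p) / 32.0
    hi = (30.0 * c + 5.0 * p - 3.0 * m) / 32.0
    return _interleave(lo, hi, axis)


# ---------------------------------------------------------------------------
# level-wise gather / scatter
# ---------------------------------------------------------------------------

def gather_patch(level: Level, lo: Sequence[int], hi: Sequence[int],
                 name: str, nghost: int = 0) -> np.ndarray:
    """Assemble a rectangular patch of level data over the index box
    ``[lo - nghost, hi + nghost]`` (inclusive, level index space).

    Cells are taken from block interiors where covered, from block ghost
    layers otherwise, and any remaining uncovered cells are filled with the
    nearest available value (the documented local order degradation at
    physical boundaries).
    """
    nd = len(lo)
    glo = [l - nghost for l in lo]
    ghi = [h + nghost for h in hi]
    shape = tuple(gh - gl + 1 for gl, gh in zip(glo, ghi))
    out = np.full(shape, np.nan, dtype=np.float64)

    def _overlap(blo, bhi):
        olo = [max(a, b) for a, b in zip(glo, blo)]
        ohi = [min(a, b) for a, b in zip(ghi, bhi)]
        if any(a > b for a, b in zip(olo, ohi)):
            return None
        dst = tuple(slice(a - g, b - g + 1) for a, b, g in zip(olo, ohi, glo))
        return olo, ohi, dst

    for b in level.blocks:
        ov = _overlap(b.lo, b.hi)
        if ov is None:
            continue
        olo, ohi, dst = ov
        src = tuple(slice(a - l + 1, b - l + 2)
                    for a, b, l in zip(olo, ohi, b.lo))
        out[dst] = b.data[name][src]
    if np.isnan(out).any():
        # second pass: block ghost layers
        for b in level.blocks:
            ov = _overlap([l - 1 for l in b.lo], [h + 1 for h in b.hi])
            if ov is None:
                continue
            olo, ohi, dst = ov
            src = tuple(slice(a - l + 1, b_ - l + 2)
                        for a, b_, l in zip(olo, ohi, b.lo))
            sub = out[dst]
            np.copyto(sub, b.data[name][src], where=np.isnan(sub))
    mask = np.isnan(out)
    if mask.any():
        idx = distance_transform_edt(mask, return_distances=False,
                                     return_indices=True)
        out = out[tuple(idx)]
    return out


def scatter_to_level(level: Level, lo: Sequence[int], hi: Sequence[int],
                     name: str, arr: np.ndarray) -> None:
    """Write ``arr`` (covering index box [lo, hi]) into level block interiors."""
    for b in level.blocks:
        olo = [max(a, c) for a, c in zip(lo, b.lo)]
        ohi = [min(a, c) for a, c in zip(hi, b.hi)]
        if any(a > c for a, c in zip(olo, ohi)):
            continue
        src = tuple(slice(a - l, c - l + 1) for a, c, l in zip(olo, ohi, lo))
        dst = tuple(slice(a - l + 1, c - l + 2)
                    for a, c, l in zip(olo, ohi, b.lo))
        b.data[name][dst] = arr[src]


def coarse_box(block: Block) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Projection of a (2-aligned) fine block onto the parent index space."""
    clo = tuple((l + 1) // 2 for l in block.lo)
    chi = tuple(h // 2 for h in block.hi)
    return clo, chi


def restrict_level_to_coarse(h: MeshHierarchy, kappa: int,
                             names: Iterable[str]) -> None:
    """Average level-``kappa`` data down into level ``kappa-1`` (overlap only)."""
    fine = h.level(kappa)
    coarse = h.level(kappa - 1)
    names = list(names)
    for b in fine.blocks:
        clo, chi = coarse_box(b)
        for name in names:
            scatter_to_level(coarse, clo, chi, name,
                             restrict_avg(b.interior(name)))


def prolong_correction_to_level(h: MeshHierarchy, kappa: int, src: str,
                                dst: str, add: bool = True) -> None:
    """Interpolate coarse field ``src`` (level kappa-1) linearly onto level
    ``kappa`` and add it to (or overwrite) fine field ``dst``."""
    fine = h.level(kappa)
    coarse = h.level(kappa - 1)
    for b in fine.blocks:
        clo, chi = coarse_box(b)
        patch = gather_patch(coarse, clo, chi, src, nghost=1)
        val = prolong_linear(patch)
        if add:
            b.interior(dst)[...] += val
        else:
            b.interior(dst)[...] = val


def fmg_interp_to_level(h: MeshHierarchy, kappa: int,
                        names: Iterable[str]) -> None:
    """Cubic FMG interpolation of coarse fields onto level ``kappa``."""
    fine = h.level(kappa)
    coarse = h.level(kappa - 1)
    for b in fine.blocks:
        clo, chi = coarse_box(b)
        for name in names:
            patch = gather_patch(coarse, clo, chi, name, nghost=2)
            b.interior(name)[...] = fmg_interp_cubic(patch)


# ---------------------------------------------------------------------------
# ghost filling
# ---------------------------------------------------------------------------

def _face_on_boundary(h: MeshHierarchy, kappa: int, block: Block,
                      axis: int, side: int) -> bool:
    n_axis = h.ncells_axis(kappa)
    if side == 0:
        return block.lo[axis] == 1
    return block.hi[axis] == n_axis[axis]


def fill_ghost_quadratic(h: MeshHierarchy, kappa: int,
                         names: Iterable[str]) -> None:
    """Quadratic coarse-fine ghost interpolation for every block of level
    ``kappa`` (> kappa_min), then same-level exchange.

    Physical-boundary faces are left untouched (``apply_physical_bcs``
    handles them).
    """
    names = list(names)
    if kappa <= h.kappa_min:
        return
    fine = h.level(kappa)
    coarse = h.level(kappa - 1)
    nd = h.ndim
    for b in fine.blocks:
        clo, chi = coarse_box(b)
        shape = b.shape
        patches = {name: gather_patch(coarse, clo, chi, name, nghost=2)
                   for name in names}
        phys = [(_face_on_boundary(h, kappa, b, a, 0),
                 _face_on_boundary(h, kappa, b, a, 1)) for a in range(nd)]

        # --- face ghosts -------------------------------------------------
        for a in range(nd):
            for side in (0, 1):
                if phys[a][side]:
                    continue
                tang = [ax for ax in range(nd) if ax != a]
                # coarse slab just outside the face, one tangential ghost ring
                idx = []
                for ax in range(nd):
                    if ax == a:
                        idx.append(1 if side == 0 else -2)
                    else:
                        idx.append(slice(1, -1))
                tsl = tuple(slice(1, -1) for _ in tang)
                for name in names:
                    inter = patches[name][tuple(idx)]
                    for k in range(len(tang)):
                        inter = _quad_tangential_axis(inter, k)
                    arr = b.data[name]
                    if side == 0:
                        i1, i2, gi = 1, 2, 0
                    else:
                        i1, i2, gi = -2, -3, -1
                    f1 = _drop_axis(_axslice(arr, a, _unit_slice(i1)), a)[tsl]
                    if shape[a] >= 2:
                        f2 = _drop_axis(_axslice(arr, a, _unit_slice(i2)), a)[tsl]
                        ghost = (8.0 * inter + 10.0 * f1 - 3.0 * f2) / 15.0
                    else:
                        ghost = (2.0 * inter + f1) / 3.0
                    dst = [slice(1, -1)] * nd
                    dst[a] = _unit_slice(gi)
                    _assign_drop(arr, tuple(dst), a, ghost)

        # --- edge / corner ghosts ---------------------------------------
        for out_axes, sides in _outside_combos(nd):
            if len(out_axes) < 2:
                continue
            if any(phys[a][s] for a, s in zip(out_axes, sides)):
                continue
            tang = [ax for ax in range(nd) if ax not in out_axes]
            # nearest outside coarse cell along the diagonal
            cidx = []
            for ax in range(nd):
                if ax in out_axes:
                    s = sides[out_axes.index(ax)]
                    cidx.append(1 if s == 0 else -2)
                else:
                    cidx.append(slice(1, -1))
            for name in names:
                cline = patches[name][tuple(cidx)]
                for k, ax in enumerate(tang):
                    cline = _quad_tangential_axis(cline, k)
                arr = b.data[name]
                idx1 = []
                idx2 = []
                gidx = []
                for ax in range(nd):
                    if ax in out_axes:
                        s = sides[out_axes.index(ax)]
                        if s == 0:
                            idx1.append(1); idx2.append(2); gidx.append(0)
                        else:
                            idx1.append(-2); idx2.append(-3); gidx.append(-1)
                    else:
                        idx1.append(slice(1, -1))
                        idx2.append(slice(1, -1))
                        gidx.append(slice(1, -1))
                f1 = arr[tuple(idx1)]
                min_ext = min(shape[ax] for ax in out_axes)
                if min_ext >= 2:
                    f2 = arr[tuple(idx2)]
                    ghost = (8.0 * cline + 10.0 * f1 - 3.0 * f2) / 15.0
                else:
                    ghost = (2.0 * cline + f1) / 3.0
                arr[tuple(gidx)] = ghost

    exchange_same_level(h, kappa, names)


def _unit_slice(i: int) -> slice:
    """Width-one slice at index ``i`` that also works for negative indices."""
    return slice(i, i + 1 if i != -1 else None)


def _drop_axis(arr: np.ndarray, axis: int) -> np.ndarray:
    """Remove a singleton axis produced by a width-1 slice."""
    return np.squeeze(arr, axis=axis)


def _assign_drop(arr: np.ndarray, dst: tuple, axis: int,
                 value: np.ndarray) -> None:
    sub = arr[dst]
    arr[dst] = value.reshape(sub.shape)


def _outside_combos(nd: int):
    """All (axes, sides) combinations of ghost regions outside the block."""
    from itertools import combinations, product
    for r in range(2, nd + 1):
        for axes in combinations(range(nd), r):
            for sides in product((0, 1), repeat=r):
                yield list(axes), list(sides)


def exchange_same_level(h: MeshHierarchy, kappa: int,
                        names: Iterable[str]) -> None:
    """Overwrite ghost cells that fall on a same-level neighbor's interior
    with that neighbor's cell-centered data."""
    names = list(names)
    level = h.level(kappa)
    if len(level.blocks) < 2:
        return
    for b in level.blocks:
        plo = [l - 1 for l in b.lo]
        phi = [x + 1 for x in b.hi]
        for nb in level.blocks:
            if nb is b:
                continue
            olo = [max(a, c) for a, c in zip(plo, nb.lo)]
            ohi = [min(a, c) for a, c in zip(phi, nb.hi)]
            if any(a > c for a, c in zip(olo, ohi)):
                continue
            dst = tuple(slice(a - l, c - l + 1)
                        for a, c, l in zip(olo, ohi, plo))
            src = tuple(slice(a - l + 1, c - l + 2)
                        for a, c, l in zip(olo, ohi, nb.lo))
            for name in names:
                b.data[name][dst] = nb.data[name][src]


def apply_physical_bcs(h: MeshHierarchy, kappa: int,
                       bcs: dict[str, BC]) -> None:
    """Fill ghost layers on faces lying on the physical boundary.

    Neumann (no-flux): ghost mirrors the interior neighbor.  Dirichlet with
    boundary value v: ghost = 2v - interior (second-order cell-centered
    convention).
    """
    level = h.level(kappa)
    nd = h.ndim
    for b in level.blocks:
        for a in range(nd):
            for side in (0, 1):
                if not _face_on_boundary(h, kappa, b, a, side):
                    continue
                gi = 0 if side == 0 else -1
                ii = 1 if side == 0 else -2
                g = [slice(None)] * nd
                i = [slice(None)] * nd
                g[a] = gi
                i[a] = ii
                for name, bc in bcs.items():
                    if name not in b.data:
                        continue
                    arr = b.data[name]
                    if bc[0] == "neumann":
                        arr[tuple(g)] = arr[tuple(i)]
                    elif bc[0] == "dirichlet":
                        arr[tuple(g)] = 2.0 * bc[1] - arr[tuple(i)]
                    else:  # pragma: no cover
                        raise ValueError(f"unknown bc {bc}")


def fill_level_ghosts(h: MeshHierarchy, kappa: int,
                      bcs: dict[str, BC]) -> None:
    """Complete ghost update for one level: coarse-fine quadratic
    interpolation, same-level exchange, then physical boundary conditions."""
    blocks = h.level(kappa).blocks
    if not blocks:
        return
    names = [nm for nm in bcs if nm in blocks[0].data]
    if kappa > h.kappa_min:
        fill_ghost_quadratic(h, kappa, names)
    apply_physical_bcs(h, kappa, {nm: bcs[nm] for nm in names})
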