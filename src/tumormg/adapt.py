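"""Refinement flagging, signature-based block clustering, and regridding.

Cells are tagged for refinement with the undivided gradient test: a cell is
flagged when the sum of squared undivided centered differences of an
indicative variable (by default the total tumor fraction, which tracks the
diffuse interface) exceeds a critical value ``C_kappa``.  Flags are buffered
by 4 cells per direction (a 9x9x9 cube per flag, clipped at external and
block boundaries), then organised into rectangular blocks with a
Berger-Rigoutsos-style signature clustering:

1. accept a block whose flagged-cell efficiency reaches ``threshold_eff`` or
   whose size is at most twice ``threshold_size``;
2. otherwise split at the zero-signature gap nearest the center, scanning
   the longest axis first;
3. failing that, split at the signature's second-difference inflection
   nearest the center;
4. failing that, accept if efficiency reaches ``min_eff``, else bisect the
   longest axis at its midpoint;
5. trim empty edge slices of every newly created block and repeat.

``regrid_transfer`` migrates data onto the regenerated fine level: current
data by cubic interpolation from the coarse grid, previous-time data copied
from overlapping old fine cells (interpolated from coarse elsewhere), and
data of vacated fine cells averaged down onto the coarse grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import maximum_filter

from .mesh import Block, Level, MeshHierarchy
from . import transfer as tr

__all__ = [
    "FlagSet",
    "BlockList",
    "flag_undivided_gradient",
    "flag_truncation_error",
    "buffer_flags",
    "generate_blocks",
    "regrid_transfer",
]


@dataclass
class FlagSet:
    """Flagged cell coordinates on one level (level index space, 1-based)."""

    kappa: int
    cells: set = field(default_factory=set)

    def __len__(self):
        return len(self.cells)

    def __bool__(self):
        return bool(self.cells)


@dataclass
class BlockList:
    """Corner index pairs of the blocks generated for level ``kappa``."""

    kappa: int
    boxes: list = field(default_factory=list)  # [(lo tuple, hi tuple), ...]

    def __len__(self):
        return len(self.boxes)

    def __iter__(self):
        return iter(self.boxes)


# ---------------------------------------------------------------------------
# flagging
# ---------------------------------------------------------------------------

def flag_undivided_gradient(h: MeshHierarchy, kappa: int, name: str,
                            C_kappa: float) -> FlagSet:
    """Undivided gradient test on level ``kappa``.

    Flags cells where the sum over axes of
    ``(psi_{i+1} - psi_{i-1})**2`` exceeds ``C_kappa`` (no division by the
    mesh spacing; the comparison is against ``C_kappa`` itself, not its
    square).  Ghost layers of ``name`` must be current.
    """
    flags = FlagSet(kappa=kappa)
    nd = h.ndim
    for b in h.level(kappa).blocks:
        arr = b.data[name]
        g2 = np.zeros(b.shape)
        for a in range(nd):
            hi = tr._axslice(arr, a, slice(2, None))
            lo = tr._axslice(arr, a, slice(0, -2))
            diff = hi - lo
            other = tuple(slice(1, -1) if ax != a else slice(None)
                          for ax in range(nd))
            g2 += diff[other] ** 2
        idx = np.argwhere(g2 > C_kappa)
        for c in idx:
            flags.cells.add(tuple(int(i) + l for i, l in zip(c, b.lo)))
    return flags


def flag_truncation_error(h: MeshHierarchy, kappa: int, name: str,
                          apply_op, threshold: float) -> FlagSet:
    """Relative truncation error test between levels ``kappa`` and
    ``kappa - 1``: flags fine cells whose parent cell has
    ``|L_{k-1}(R psi) - R L_k(psi)| > threshold``.

    ``apply_op(h, kappa, in_name, out_name)`` evaluates the level operator.
    Provided as the alternative refinement criterion; off by default.
    """
    flags = FlagSet(kappa=kappa)
    if not np.isfinite(threshold):
        return flags
    fine = h.level(kappa)
    coarse = h.level(kappa - 1)
    # R L_k(psi) and L_{k-1}(R psi)
    apply_op(h, kappa, name, "_Lpsi")
    for b in fine.blocks:
        clo, chi = tr.coarse_box(b)
        RL = tr.restrict_avg(b.interior("_Lpsi"))
        Rpsi = tr.restrict_avg(b.interior(name))
        tmp = "_Rpsi_tmp"
        for cb in coarse.blocks:
            if tmp not in cb.data:
                cb.data[tmp] = cb.data[name].copy()
        tr.scatter_to_level(coarse, clo, chi, tmp, Rpsi)
        apply_op(h, kappa - 1, tmp, "_LRpsi")
        LR = tr.gather_patch(coarse, clo, chi, "_LRpsi")
        tau = LR - RL
        idx = np.argwhere(np.abs(tau) > threshold)
        for c in idx:
            parent = tuple(int(i) + l for i, l in zip(c, clo))
            # flag the 2^d fine children of the offending coarse cell
            rngs = [range(2 * p - 1, 2 * p + 1) for p in parent]
            from itertools import product
            for child in product(*rngs):
                if b.contains_cell(child):
                    flags.cells.add(child)
        for cb in coarse.blocks:
            cb.data.pop(tmp, None)
            cb.data.pop("_LRpsi", None)
    for b in fine.blocks:
        b.data.pop("_Lpsi", None)
    return flags


def buffer_flags(flags: FlagSet, radius: int = 4,
                 bounds: Sequence[int] | None = None,
                 valid_boxes: Sequence | None = None) -> FlagSet:
    """Buffer every flag by ``radius`` cells per side and axis (a
    ``(2r+1)^d`` cube per flag), clipped to the domain index range
    ``1..bounds[a]`` and, when given, to the union of ``valid_boxes``
    (lo, hi pairs — the cells that exist on the level)."""
    if not flags:
        return FlagSet(kappa=flags.kappa)
    cells = np.array(sorted(flags.cells), dtype=int)
    lo = cells.min(axis=0) - radius
    hi = cells.max(axis=0) + radius
    if bounds is not None:
        lo = np.maximum(lo, 1)
        hi = np.minimum(hi, np.asarray(bounds, dtype=int))
    shape = tuple(hi - lo + 1)
    mask = np.zeros(shape, dtype=bool)
    inb = np.all((cells >= lo) & (cells <= hi), axis=1)
    pts = cells[inb] - lo
    mask[tuple(pts.T)] = True
    mask = maximum_filter(mask, size=2 * radius + 1, mode="constant")
    if valid_boxes is not None:
        valid = np.zeros(shape, dtype=bool)
        for blo, bhi in valid_boxes:
            olo = np.maximum(lo, blo)
            ohi = np.minimum(hi, bhi)
            if np.any(olo > ohi):
                continue
            sl = tuple(slice(a - l, b - l + 1)
                       for a, b, l in zip(olo, ohi, lo))
            valid[sl] = True
        mask &= valid
    out = FlagSet(kappa=flags.kappa)
    for c in np.argwhere(mask):
        out.cells.add(tuple(int(i) + int(l) for i, l in zip(c, lo)))
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _trim(mask, lo, hi):
    """Remove empty edge slices; returns (lo, hi) or None if empty."""
    lo = list(lo)
    hi = list(hi)
    sub = mask[tuple(slice(a, b + 1) for a, b in zip(lo, hi))]
    if not sub.any():
        return None
    for a in range(mask.ndim):
        axes = tuple(ax for ax in range(mask.ndim) if ax != a)
        sig = sub.sum(axis=axes)
        nz = np.nonzero(sig)[0]
        lo[a] += int(nz[0])
        hi[a] -= int(len(sig) - 1 - nz[-1])
        sub = mask[tuple(slice(x, y + 1) for x, y in zip(lo, hi))]
    return tuple(lo), tuple(hi)


def _axes_longest_first(lo, hi):
    ext = [h - l + 1 for l, h in zip(lo, hi)]
    # longest first; ties broken x -> y -> z (lower axis index first)
    return sorted(range(len(ext)), key=lambda a: (-ext[a], a))


def _closest_to_center(candidates, center):
    # ties broken toward the lower index
    return min(candidates, key=lambda i: (abs(i - center), i))


def generate_blocks(flags: FlagSet, threshold_eff: float = 0.9,
                    threshold_size: int = 1000,
                    min_eff: float = 0.5) -> BlockList:
    """Cluster flagged level-``kappa`` cells into blocks for level
    ``kappa + 1`` (indices doubled onto the finer index space)."""
    out = BlockList(kappa=flags.kappa + 1)
    if not flags:
        return out
    cells = np.array(sorted(flags.cells), dtype=int)
    origin = cells.min(axis=0)
    top = cells.max(axis=0)
    mask = np.zeros(tuple(top - origin + 1), dtype=bool)
    mask[tuple((cells - origin).T)] = True

    queue = [(tuple(np.zeros_like(origin)), tuple(top - origin))]
    accepted = []
    while queue:
        box = queue.pop()
        t = _trim(mask, *box)
        if t is None:
            continue
        lo, hi = t
        sub = mask[tuple(slice(a, b + 1) for a, b in zip(lo, hi))]
        size = sub.size
        eff = sub.sum() / size
        ext = [b - a + 1 for a, b in zip(lo, hi)]

        # step 1: accept by efficiency or size
        if eff >= threshold_eff or size <= 2 * threshold_size:
            accepted.append((lo, hi))
            continue

        axes = _axes_longest_first(lo, hi)
        signatures = {}
        for a in axes:
            other = tuple(ax for ax in range(mask.ndim) if ax != a)
            signatures[a] = sub.sum(axis=other)

        # step 2: zero-signature gaps (interior slices only)
        split = None
        for a in axes:
            sig = signatures[a]
            gaps = [i for i in range(1, len(sig) - 1) if sig[i] == 0]
            if gaps:
                g = _closest_to_center(gaps, (len(sig) - 1) / 2.0)
                left = (lo, tuple(hi[ax] if ax != a else lo[a] + g - 1
                                  for ax in range(mask.ndim)))
                right = (tuple(lo[ax] if ax != a else lo[a] + g + 1
                               for ax in range(mask.ndim)), hi)
                split = [left, right]
                break
        if split is not None:
            queue.extend(split)
            continue

        # step 3: inflection of the signature's second difference
        for a in axes:
            sig = signatures[a].astype(np.int64)
            if len(sig) < 4:
                continue
            d2 = sig[:-2] - 2 * sig[1:-1] + sig[2:]  # d2[i] ~ slice i+1
            cand = [i + 1 for i in range(len(d2) - 1)
                    if d2[i] * d2[i + 1] < 0]
            if cand:
                c = _closest_to_center(cand, (len(sig) - 1) / 2.0)
                left = (lo, tuple(hi[ax] if ax != a else lo[a] + c
                                  for ax in range(mask.ndim)))
                right = (tuple(lo[ax] if ax != a else lo[a] + c + 1
                               for ax in range(mask.ndim)), hi)
                split = [left, right]
                break
        if split is not None:
            queue.extend(split)
            continue

        # step 4: accept at min efficiency, else bisect the longest axis
        if eff >= min_eff:
            accepted.append((lo, hi))
            continue
        a = axes[0]
        mid = lo[a] + ext[a] // 2 - 1
        left = (lo, tuple(hi[ax] if ax != a else mid
                          for ax in range(mask.ndim)))
        right = (tuple(lo[ax] if ax != a else mid + 1
                       for ax in range(mask.ndim)), hi)
        queue.extend([left, right])

    for lo, hi in accepted:
        glo = tuple(int(l + o) for l, o in zip(lo, origin))
        ghi = tuple(int(h + o) for h, o in zip(hi, origin))
        # double onto the finer index space (parent cell c -> fine 2c-1..2c)
        out.boxes.append((tuple(2 * c - 1 for c in glo),
                          tuple(2 * c for c in ghi)))
    return out


# ---------------------------------------------------------------------------
# regridding
# ---------------------------------------------------------------------------

def regrid_transfer(h: MeshHierarchy, kappa: int, new_blocks: BlockList,
                    fields: Iterable[str], old_fields: Iterable[str],
                    restrict_fields: Iterable[str] | None = None) -> None:
    """Replace level ``kappa`` with ``new_blocks`` and migrate data.

    * every current-time field on the new blocks is cubically interpolated
      from level ``kappa - 1``;
    * previous-time fields (``old_fields``) are copied where new cells
      overlap old fine cells and cubically interpolated from coarse where
      they do not;
    * old fine cells not covered by any new block have their data averaged
      down onto the coarse level before the old level is dropped
      (``restrict_fields`` limits which fields are averaged down; by default
      all of them — pass a subset when the coarse level already carries
      newer data, e.g. when regridding mid-solve).

    New blocks must nest in the coarse level's block union.
    """
    fields = list(fields)
    old_fields = list(old_fields)
    restrict_fields = (fields + old_fields if restrict_fields is None
                       else list(restrict_fields))
    coarse = h.level(kappa - 1)
    old_level = h.level(kappa)
    nd = h.ndim
    _check_nesting(h, kappa, new_blocks)

    # vacated old data -> coarse (average down first; regions still covered
    # will be re-populated on the new fine level anyway)
    if old_level.blocks and restrict_fields:
        tr.restrict_level_to_coarse(h, kappa, restrict_fields)

    new_level = Level(kappa=kappa, eta=h.spacing(kappa))
    for lo, hi in new_blocks:
        b = Block(lo, hi)
        b.alloc(fields + old_fields)
        clo, chi = tr.coarse_box(b)
        for name in fields + old_fields:
            patch = tr.gather_patch(coarse, clo, chi, name, nghost=2)
            b.interior(name)[...] = tr.fmg_interp_cubic(patch)
        # previous-time data: copy from overlapping old fine cells
        for ob in old_level.blocks:
            olo = [max(a, c) for a, c in zip(b.lo, ob.lo)]
            ohi = [min(a, c) for a, c in zip(b.hi, ob.hi)]
            if any(a > c for a, c in zip(olo, ohi)):
                continue
            dst = tuple(slice(a - l + 1, c - l + 2)
                        for a, c, l in zip(olo, ohi, b.lo))
            src = tuple(slice(a - l + 1, c - l + 2)
                        for a, c, l in zip(olo, ohi, ob.lo))
            for name in old_fields:
                b.data[name][dst] = ob.data[name][src]
        new_level.blocks.append(b)
    h.levels[kappa - h.kappa_min] = new_level


def _check_nesting(h: MeshHierarchy, kappa: int, new_blocks: BlockList) -> None:
    coarse = h.level(kappa - 1)
    if kappa - 1 <= 0:
        return  # global levels cover the whole domain
    covered = np.zeros(h.ncells_axis(kappa - 1), dtype=bool)
    for cb in coarse.blocks:
        covered[tuple(slice(l - 1, x) for l, x in zip(cb.lo, cb.hi))] = True
    for lo, hi in new_blocks:
        clo = tuple((l + 1) // 2 for l in lo)
        chi = tuple(x // 2 for x in hi)
        sl = tuple(slice(l - 1, x) for l, x in zip(clo, chi))
        if not covered[sl].all():
            raise ValueError(
                f"new block {lo}-{hi} not nested in level {kappa - 1}")
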