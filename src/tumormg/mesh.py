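"""Block-structured cell-centered Cartesian mesh hierarchy.

Grid levels are numbered ``kappa = kappa_min, ..., 0, ..., kappa_max``.
Levels ``kappa <= 0`` are *global*: each consists of a single rectangular
block covering the whole computational domain, with the mesh spacing halving
from one level to the next.  Level 0 is the *root* level (the finest global
grid).  Levels ``kappa >= 1`` are *refinement* levels: each is a set of
pairwise-disjoint rectangular blocks, properly nested inside the union of the
blocks one level below, again with spacing halved per level.

Indexing follows the cell-centered convention: interior cells of a block run
``1..N`` per axis in the block-local padded arrays (``0`` and ``N+1`` are the
ghost layers), while ``Block.lo``/``Block.hi`` locate the block in the
*level-global* 1-based index space.  Cell centers sit at
``x_i = L + (i - 1/2) * eta`` and cell edges at ``x_{i+1/2} = L + i * eta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Block",
    "Level",
    "MeshHierarchy",
    "build_hierarchy",
    "cell_geometry",
    "count_dof",
    "mesh_summary",
]


class Block:
    """One rectangular patch of cells with a single ghost layer per face.

    Parameters
    ----------
    lo, hi : tuple of int
        Inclusive 1-based interior index range in the level index space.
        ``hi[a] >= lo[a]`` for every axis ``a``.
    """

    __slots__ = ("lo", "hi", "data", "face_data")

    def __init__(self, lo: Sequence[int], hi: Sequence[int]):
        self.lo = tuple(int(x) for x in lo)
        self.hi = tuple(int(x) for x in hi)
        if any(h < l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"empty block extents lo={lo} hi={hi}")
        # cell-centered arrays, shape interior+2 per axis (ghost width 1)
        self.data: dict[str, np.ndarray] = {}
        # face-centered arrays: name -> tuple of per-axis arrays
        self.face_data: dict[str, tuple[np.ndarray, ...]] = {}

    @property
    def ndim(self) -> int:
        return len(self.lo)

    @property
    def shape(self) -> tuple[int, ...]:
        """Interior cell counts per axis."""
        return tuple(h - l + 1 for l, h in zip(self.lo, self.hi))

    @property
    def ncells(self) -> int:
        return int(np.prod(self.shape))

    def alloc(self, names: Iterable[str], fill: float = 0.0) -> None:
        """Allocate (or reset) cell-centered arrays, ghosts included."""
        padded = tuple(n + 2 for n in self.shape)
        for name in names:
            self.data[name] = np.full(padded, fill, dtype=np.float64)

    def alloc_faces(self, names: Iterable[str], fill: float = 0.0) -> None:
        """Allocate face-centered arrays (one per axis, no ghosts).

        Axis-``a`` faces have shape = interior shape with axis ``a`` extent
        ``N_a + 1`` (edge sets E_ew / E_ns / E_tb).
        """
        for name in names:
            arrs = []
            for a in range(self.ndim):
                shp = list(self.shape)
                shp[a] += 1
                arrs.append(np.full(tuple(shp), fill, dtype=np.float64))
            self.face_data[name] = tuple(arrs)

    def interior(self, name: str) -> np.ndarray:
        """View of the interior cells of a stored array."""
        return self.data[name][(slice(1, -1),) * self.ndim]

    def contains_cell(self, idx: Sequence[int]) -> bool:
        return all(l <= i <= h for i, l, h in zip(idx, self.lo, self.hi))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Block(lo={self.lo}, hi={self.hi})"


@dataclass
class Level:
    """One grid level: a spacing and a list of non-overlapping blocks."""

    kappa: int
    eta: float
    blocks: list[Block] = field(default_factory=list)

    @property
    def ndim(self) -> int:
        return self.blocks[0].ndim if self.blocks else 0

    @property
    def ncells(self) -> int:
        return sum(b.ncells for b in self.blocks)

    def alloc(self, names: Iterable[str], fill: float = 0.0) -> None:
        names = list(names)
        for b in self.blocks:
            b.alloc(names, fill)


class MeshHierarchy:
    """Ordered set of grid levels ``kappa_min..kappa_max`` over one domain.

    ``domain`` is a tuple of per-axis ``(L, R)`` bounds; the number of axes
    fixes the spatial dimension (2 or 3).
    """

    def __init__(
        self,
        domain: Sequence[tuple[float, float]],
        root_cells: Sequence[int],
        kappa_min: int,
        kappa_max: int,
    ):
        self.domain = tuple((float(l), float(r)) for l, r in domain)
        self.root_cells = tuple(int(n) for n in root_cells)
        self.kappa_min = int(kappa_min)
        self.kappa_max = int(kappa_max)
        if self.kappa_min > 0 or self.kappa_max < 0:
            raise ValueError("require kappa_min <= 0 <= kappa_max")
        self.levels: list[Level] = []
        for kappa in range(self.kappa_min, self.kappa_max + 1):
            self.levels.append(Level(kappa=kappa, eta=self.spacing(kappa)))

    # -- geometry ---------------------------------------------------------
    @property
    def ndim(self) -> int:
        return len(self.domain)

    def spacing(self, kappa: int) -> float:
        L, R = self.domain[0]
        return (R - L) / self.ncells_axis(kappa)[0]

    def ncells_axis(self, kappa: int) -> tuple[int, ...]:
        """Per-axis cell count of the uniform index space of level ``kappa``."""
        if kappa >= 0:
            return tuple(n * 2**kappa for n in self.root_cells)
        return tuple(n // 2 ** (-kappa) for n in self.root_cells)

    def level(self, kappa: int) -> Level:
        return self.levels[kappa - self.kappa_min]

    def kappas(self) -> range:
        return range(self.kappa_min, self.kappa_max + 1)

    def finest_active(self) -> int:
        """Finest level that currently holds any blocks."""
        top = self.kappa_min
        for kappa in self.kappas():
            if self.level(kappa).blocks:
                top = kappa
        return top

    def alloc(self, names: Iterable[str], fill: float = 0.0) -> None:
        names = list(names)
        for lev in self.levels:
            lev.alloc(names, fill)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = [f"k={lev.kappa}:{len(lev.blocks)} blocks" for lev in self.levels]
        return f"MeshHierarchy({', '.join(parts)})"


def build_hierarchy(
    domain: Sequence[tuple[float, float]],
    root_cells: Sequence[int],
    n_coarse_global: int,
    kappa_max: int,
) -> MeshHierarchy:
    """Create a hierarchy with populated global levels and empty refinement levels.

    Parameters
    ----------
    domain : per-axis (L, R) bounds.
    root_cells : cells per axis on the root level (kappa = 0).
    n_coarse_global : number of global levels (kappa = kappa_min..0), so
        ``kappa_min = -(n_coarse_global - 1)``.
    kappa_max : finest admissible refinement level (>= 0).

    Raises
    ------
    ValueError
        If ``root_cells`` is not divisible by ``2**(n_coarse_global-1)`` on
        every axis, or the cells are not cubic (unequal spacing across axes).
    """
    if n_coarse_global < 1:
        raise ValueError("need at least one global level")
    domain = tuple((float(l), float(r)) for l, r in domain)
    root_cells = tuple(int(n) for n in root_cells)
    if len(domain) != len(root_cells):
        raise ValueError("domain / root_cells dimension mismatch")
    div = 2 ** (n_coarse_global - 1)
    for n in root_cells:
        if n % div != 0 or n // div < 1:
            raise ValueError(
                f"root cell count {n} not divisible by {div} "
                f"(needed for {n_coarse_global} global levels)"
            )
    spacings = [(r - l) / n for (l, r), n in zip(domain, root_cells)]
    if not np.allclose(spacings, spacings[0], rtol=1e-12, atol=0.0):
        raise ValueError(f"anisotropic spacing {spacings}; cubic cells required")

    h = MeshHierarchy(domain, root_cells, kappa_min=-(n_coarse_global - 1),
                      kappa_max=kappa_max)
    for kappa in range(h.kappa_min, 1):
        n_axis = h.ncells_axis(kappa)
        h.level(kappa).blocks = [Block((1,) * h.ndim, n_axis)]
    return h


def cell_geometry(level: Level, block: Block, domain: Sequence[tuple[float, float]]):
    """Coordinate arrays of cell centers (ghosts included) and cell edges.

    Returns ``(centers, edges)``: per-axis arrays with
    ``centers[a][j] = L_a + (i - 1/2) eta`` for ``i = lo-1 .. hi+1`` and
    ``edges[a][j] = L_a + i eta`` for ``i = lo-1 .. hi``.
    """
    if block not in level.blocks:
        raise ValueError("block does not belong to level")
    eta = level.eta
    centers, edges = [], []
    for a in range(block.ndim):
        L = domain[a][0]
        i = np.arange(block.lo[a] - 1, block.hi[a] + 2, dtype=np.float64)
        centers.append(L + (i - 0.5) * eta)
        ie = np.arange(block.lo[a] - 1, block.hi[a] + 1, dtype=np.float64)
        edges.append(L + ie * eta)
    return centers, edges


def count_dof(h: MeshHierarchy) -> int:
    """Total interior cell count over all blocks of all levels.

    Ghost layers and external boundary cells are excluded; coarse cells
    underneath refined blocks *are* counted (all levels are summed).
    """
    return sum(lev.ncells for lev in h.levels)


def mesh_summary(h: MeshHierarchy) -> dict:
    """JSON-serializable summary: per-level spacing, block corners, DOF."""
    out = {
        "domain": [list(b) for b in h.domain],
        "kappa_min": h.kappa_min,
        "kappa_max": h.kappa_max,
        "dof": count_dof(h),
        "levels": [],
    }
    for lev in h.levels:
        entry = {
            "kappa": lev.kappa,
            "eta": lev.eta,
            "n_blocks": len(lev.blocks),
            "dof": lev.ncells,
            "blocks": [],
        }
        for b in lev.blocks:
            lo_xyz = [h.domain[a][0] + (b.lo[a] - 1) * lev.eta for a in range(h.ndim)]
            hi_xyz = [h.domain[a][0] + b.hi[a] * lev.eta for a in range(h.ndim)]
            entry["blocks"].append(
                {"lo": list(b.lo), "hi": list(b.hi),
                 "corner_lo": lo_xyz, "corner_hi": hi_xyz}
            )
        out["levels"].append(entry)
    return out


def write_mesh_summary(h: MeshHierarchy, path) -> None:
    with open(path, "w") as f:
        json.dump(mesh_summary(h), f, indent=2)
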