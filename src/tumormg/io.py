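"""File output: VTK image-data fields, HDF5 checkpoints, CSV logs.

One legacy-ASCII VTK ``STRUCTURED_POINTS`` file is written per block (cell
data), which external tools assemble into composite views; checkpoints are
single HDF5 files holding the full hierarchy layout and every padded array
bit-exactly, so write/read round-trips are lossless and restarts reproduce
non-restarted runs.
"""

from __future__ import annotations

import csv
import json
import os

import h5py
import numpy as np

from .mesh import Block, MeshHierarchy

__all__ = ["write_vtk", "write_checkpoint", "read_checkpoint",
           "write_csv_log"]


def write_vtk(h: MeshHierarchy, prefix, fields, label: str = "") -> list:
    """Write one VTK file per block; returns the file paths."""
    paths = []
    os.makedirs(os.path.dirname(str(prefix)) or ".", exist_ok=True)
    for lev in h.levels:
        for ib, b in enumerate(lev.blocks):
            path = f"{prefix}_L{lev.kappa}_B{ib}{label}.vtk"
            _write_vtk_block(path, h, lev, b, fields)
            paths.append(path)
    return paths


def _write_vtk_block(path, h, lev, b: Block, fields) -> None:
    nd = h.ndim
    shape = b.shape + (1,) * (3 - nd)
    origin = [h.domain[a][0] + (b.lo[a] - 1) * lev.eta for a in range(nd)]
    origin += [0.0] * (3 - nd)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"tumormg level {lev.kappa} block {b.lo}-{b.hi}\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {shape[0] + 1} {shape[1] + 1} {shape[2] + 1}\n")
        f.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        f.write(f"SPACING {lev.eta} {lev.eta} {lev.eta}\n")
        ncell = int(np.prod(shape))
        f.write(f"CELL_DATA {ncell}\n")
        for name in fields:
            if name not in b.data:
                continue
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            arr = b.interior(name).reshape(b.shape + (1,) * (3 - nd))
            # VTK orders x fastest
            flat = np.transpose(arr, (2, 1, 0)).ravel()
            np.savetxt(f, flat.reshape(-1, 1), fmt="%.17g")


def write_checkpoint(h: MeshHierarchy, path, config_echo: dict | None = None,
                     extra: dict | None = None) -> None:
    """Lossless HDF5 checkpoint of the hierarchy and all cell arrays."""
    with h5py.File(path, "w") as f:
        f.attrs["domain"] = np.asarray(h.domain)
        f.attrs["root_cells"] = np.asarray(h.root_cells)
        f.attrs["kappa_min"] = h.kappa_min
        f.attrs["kappa_max"] = h.kappa_max
        f.attrs["config"] = json.dumps(config_echo or {})
        f.attrs["extra"] = json.dumps(extra or {})
        for lev in h.levels:
            g = f.create_group(f"level_{lev.kappa}")
            g.attrs["kappa"] = lev.kappa
            g.attrs["eta"] = lev.eta
            for ib, b in enumerate(lev.blocks):
                gb = g.create_group(f"block_{ib:04d}")
                gb.create_dataset("lo", data=np.asarray(b.lo))
                gb.create_dataset("hi", data=np.asarray(b.hi))
                gd = gb.create_group("data")
                for name, arr in b.data.items():
                    gd.create_dataset(name, data=arr)


def read_checkpoint(path):
    """Rebuild (hierarchy, config_echo) from a checkpoint file."""
    with h5py.File(path, "r") as f:
        domain = [tuple(x) for x in f.attrs["domain"]]
        h = MeshHierarchy(domain, tuple(int(x) for x in f.attrs["root_cells"]),
                          int(f.attrs["kappa_min"]), int(f.attrs["kappa_max"]))
        cfg = json.loads(f.attrs["config"])
        for lev in h.levels:
            g = f[f"level_{lev.kappa}"]
            for key in sorted(g.keys()):
                gb = g[key]
                b = Block(tuple(int(x) for x in gb["lo"][...]),
                          tuple(int(x) for x in gb["hi"][...]))
                for name, ds in gb["data"].items():
                    b.data[name] = ds[...]
                lev.blocks.append(b)
    return h, cfg


def write_csv_log(rows: list[dict], path) -> None:
    if not rows:
        with open(path, "w") as f:
            f.write("")
        return
    keys = list(rows[0].keys())
    with open(path, "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=keys)
        w.writeheader()
        w.writerows(rows)
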