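"""End-to-end simulation driver, fixtures, and the convergence study.

A run starts from a rectangular viable-cell seed (phi_V = 0.65) in a
uniform ECM background (phi_E = 0.35) and advances the coupled system with
fixed time step theta: each step freezes the old-time sources, pressure and
velocities, solves the Crank-Nicolson cell/ECM system with the adaptive
FAS-FMG multigrid (flagging / clustering / regridding happens inside the
FMG loop, once per level per step), then updates the quasi-steady
diffusible species and the transient MDE/myofibroblast/vessel fields on
the final hierarchy, and finally averages fine data down so every level
carries a consistent composite state.

The reduced "lite" profile (cells, ECM, potentials, pressure, oxygen,
glucose, growth/angiogenic factors, MDEs, myofibroblasts, vessels) is the
default; ions, the interstitial pressure, and ECM elasticity are the
supplement-dependent extensions enabled by the "full" profile.
"""

from __future__ import annotations

import copy

import os
from dataclasses import dataclass, field

import numpy as np

from . import adapt, io, model
from . import stencil as st
from . import transfer as tr
from .mesh import MeshHierarchy, build_hierarchy, count_dof, mesh_summary
from .params import ModelParams
from .solver import (
    ScalarLinearSystem,
    SolverConfig,
    build_ch_rhs,
    crank_nicolson_system,
    fmg_solve,
    solve_scalar,
)

__all__ = ["RunSpec", "Simulation", "initial_condition", "run_simulation",
           "convergence_study", "write_output", "fixture_generators",
           "composite_uniform"]

LITE_STATE = ["phi_V", "phi_D", "phi_E", "mu_T", "mu_E", "p",
              "n", "g", "tgf", "taf", "m", "F_E", "B_nE", "L_nE"]
FULL_EXTRA = ["q", "w", "l", "b", "a", "s", "r"]
CH_UNKNOWNS = ["phi_V", "phi_D", "phi_E", "mu_T", "mu_E"]
PARTIAL_RHS = ["rhsP_m", "rhsP_B_nE", "rhsP_L_nE"]


@dataclass
class RunSpec:
    """Configuration of one simulation run."""

    domain: tuple = ((0.0, 40.0), (0.0, 40.0), (0.0, 40.0))
    root_cells: tuple = (32, 32, 32)
    n_coarse_global: int = 3
    kappa_max: int = 2
    end_time: float = 0.5
    output_every: int = 0           # steps between snapshots (0 = final only)
    out_dir: str | None = None
    profile: str = "lite"           # "lite" | "full"
    fixture: str = "tumor"
    params: ModelParams = field(default_factory=ModelParams)
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self):
        n_steps = self.end_time / self.solver.theta
        if self.end_time <= 0 or abs(n_steps - round(n_steps)) > 1e-8:
            raise ValueError(
                "end time must be a positive multiple of the time step")
        if self.params.seed_side > min(r - l for l, r in self.domain):
            raise ValueError("seed exceeds the domain")

    @property
    def n_steps(self) -> int:
        return int(round(self.end_time / self.solver.theta))

    @property
    def state_fields(self) -> list:
        return LITE_STATE + (FULL_EXTRA if self.profile == "full" else [])


class Simulation:
    """Stateful driver: hierarchy + fields + per-step logs."""

    def __init__(self, spec: RunSpec):
        self.spec = spec
        self.prm = spec.params
        self.cfg = spec.solver
        self.t = 0.0
        self.step_index = 0
        self.cycle_log: list[dict] = []
        self.dof_log: list[dict] = []
        self.h = initial_condition(spec)

    @classmethod
    def from_checkpoint(cls, spec: RunSpec, path) -> "Simulation":
        """Resume from a checkpoint; restarted runs reproduce uninterrupted
        ones bit-identically (the model is deterministic)."""
        sim = cls.__new__(cls)
        sim.spec = spec
        sim.prm = spec.params
        sim.cfg = spec.solver
        h, echo = io.read_checkpoint(path)
        sim.h = h
        sim.t = float(echo.get("t", 0.0))
        sim.step_index = int(echo.get("step", 0))
        sim.cycle_log = []
        sim.dof_log = []
        return sim

    # -- helpers ------------------------------------------------------------
    def _active(self):
        return [k for k in self.h.kappas() if self.h.level(k).blocks]

    def _bc(self, names):
        table = model.bc_table(self.prm)
        out = {}
        for nm in names:
            base = nm[:-5] if nm.endswith("__old") else nm
            out[nm] = table[base]
        return out

    def _fill_ghosts(self, kappa, names):
        tr.fill_level_ghosts(self.h, kappa, self._bc(names))

    def _compute_sources(self, kappa, suffix=""):
        """Pointwise sources stored as padded S_* arrays on one level."""
        lev = self.h.level(kappa)
        for b in lev.blocks:
            f = {nm: b.data[nm + suffix] for nm in
                 ("n", "g", "tgf", "taf", "m", "F_E", "phi_V", "phi_D",
                  "phi_E", "B_nE", "L_nE", "p")}
            f_sp_i = model.sprout_fraction_field(self.h, kappa, b, self.prm)
            f_sp = np.zeros_like(b.data["n"])
            f_sp[(slice(1, -1),) * self.h.ndim] = f_sp_i
            # pad the octant map into ghosts by edge replication
            f_sp = _pad_edge(f_sp)
            S = model.source_terms(f, f_sp, self.prm)
            for nm, arr in S.items():
                b.data[nm] = arr
            b.data["S_total"] = S["S_V"] + S["S_D"] + S["S_E"]

    def _eff(self, f, triple, suffix=""):
        phiT = f["phi_V" + suffix] + f["phi_D" + suffix]
        phiE = f["phi_E" + suffix]
        return model.effective_coefficient(
            phiT, phiE, *triple, phi_H=1.0 - phiT - phiE,
            eps=self.prm.phiC_eps)

    # -- one time step ------------------------------------------------------
    def step(self):
        h, prm, cfg = self.h, self.prm, self.cfg
        spec = self.spec
        state = spec.state_fields
        old_state = [nm + "__old" for nm in state]

        # 1) old-time ghosts, sources, pressure, velocities
        for k in self._active():
            self._fill_ghosts(k, state)
            self._compute_sources(k)
        model.pressure_velocity_solve(h, prm, cfg,
                                      with_q=(spec.profile == "full"),
                                      tol=cfg.tol_min)
        for k in self._active():
            self._fill_ghosts(k, ["p"])
            model.compute_face_velocities(h, k, prm)

        # 2) snapshot the old time level; explicit transient contributions
        for k in self._active():
            lev = h.level(k)
            flux = model.transient_species_rhs(h, k, prm)
            for b in lev.blocks:
                for nm in state:
                    b.data[nm + "__old"] = b.data[nm].copy()
                th = cfg.theta
                f = b.data
                Dm = self._eff(f, prm.D_m)
                f["rhsP_m"] = np.zeros_like(f["m"])
                b.interior("rhsP_m")[...] = (
                    st.interior(f["m"]) / th
                    + 0.5 * st.div_mobility_grad(Dm, f["m"], lev.eta)
                    + st.interior(f["S_m"]))
                for nm, Dv in (("B_nE", prm.D_BnE), ("L_nE", prm.D_LnE)):
                    Dc = np.full_like(f[nm], Dv)
                    f[f"rhsP_{nm}"] = np.zeros_like(f[nm])
                    b.interior(f"rhsP_{nm}")[...] = (
                        st.interior(f[nm]) / th
                        + 0.5 * st.div_mobility_grad(Dc, f[nm], lev.eta)
                        + flux[id(b)][nm]
                        + st.interior(f["S_" + nm.replace("_", "", 1)]))
                # myofibroblasts: fully explicit update (no Fickian term)
                b.interior("F_E")[...] = (
                    st.interior(f["F_E"])
                    + th * (flux[id(b)]["F_E"] + st.interior(f["S_FE"])))

        # 3) Crank-Nicolson cell/ECM solve with in-loop regridding
        system = crank_nicolson_system(h, prm, cfg)
        try:
            fmg_solve(h, system, cfg, regrid_hook=self._regrid_hook(),
                      log=self.cycle_log, time_step=self.step_index)
        except Exception:
            # dump the failing state for post-mortem before propagating
            if spec.out_dir:
                os.makedirs(spec.out_dir, exist_ok=True)
                io.write_checkpoint(
                    h, os.path.join(spec.out_dir, "abort_state.h5"),
                    config_echo={"t": self.t, "step": self.step_index,
                                 "aborted": True})
            raise

        # 4) new-time diffusible species
        for k in self._active():
            self._fill_ghosts(k, state)
        model.quasi_steady_species_system(
            h, prm, cfg, with_ions=(spec.profile == "full"),
            tol=cfg.tol_min)

        # 5) implicit diffusion updates for MDEs and vessels
        for nm, dsel in (("m", "eff_m"), ("B_nE", prm.D_BnE),
                         ("L_nE", prm.D_LnE)):
            for k in self._active():
                for b in h.level(k).blocks:
                    f = b.data
                    b.alloc([f"coef_a_{nm}", f"coef_d_{nm}", f"rhs_{nm}"])
                    f[f"coef_a_{nm}"][...] = 1.0 / cfg.theta
                    if nm == "m":
                        f[f"coef_d_{nm}"][...] = 0.5 * self._eff(f, prm.D_m)
                    else:
                        f[f"coef_d_{nm}"][...] = 0.5 * dsel
                    f[f"rhs_{nm}"][...] = f[f"rhsP_{nm}"]
            bc = model.bc_table(prm)[nm]
            solve_scalar(h, ScalarLinearSystem(nm, bc), cfg, tol=cfg.tol_min)

        # 6) composite sync: fine data wins underneath refined blocks
        for k in reversed(self._active()):
            if k > h.kappa_min:
                tr.restrict_level_to_coarse(h, k, state)

        self.t += cfg.theta
        self.step_index += 1
        self.dof_log.append({"time_step": self.step_index, "time": self.t,
                             "dof": count_dof(h)})

    def _regrid_hook(self):
        h, prm, cfg, spec = self.h, self.prm, self.cfg, self.spec
        state = spec.state_fields
        old_state = [nm + "__old" for nm in state]

        def hook(kappa: int) -> bool:
            if kappa + 1 > h.kappa_max:
                return False
            lev = h.level(kappa)
            for b in lev.blocks:
                b.data["phi_T"] = b.data["phi_V"] + b.data["phi_D"]
            flags = adapt.flag_undivided_gradient(
                h, kappa, cfg.flag_variable, cfg.C_kappa)
            bl = adapt.BlockList(kappa + 1, [])
            if flags:
                bounds = h.ncells_axis(kappa)
                vboxes = ([(b.lo, b.hi) for b in lev.blocks]
                          if kappa >= 1 else None)
                flags = adapt.buffer_flags(flags, cfg.buffer_radius,
                                           bounds=bounds, valid_boxes=vboxes)
                bl = adapt.generate_blocks(flags, cfg.threshold_eff,
                                           cfg.threshold_size, cfg.min_eff)
                if kappa >= 1:
                    bl = _clip_to_parent(bl, lev)
            migr = old_state + PARTIAL_RHS
            if not bl.boxes:
                if h.level(kappa + 1).blocks:
                    adapt.regrid_transfer(h, kappa + 1, bl, fields=[],
                                          old_fields=[],
                                          restrict_fields=migr)
                for kk in range(kappa + 2, h.kappa_max + 1):
                    h.level(kk).blocks.clear()
                return False
            non_ch = [nm for nm in state if nm not in CH_UNKNOWNS]
            adapt.regrid_transfer(h, kappa + 1, bl, fields=state,
                                  old_fields=migr,
                                  restrict_fields=migr + non_ch)
            # old-time quantities on the new blocks
            tr.fill_level_ghosts(h, kappa + 1, self._bc(old_state))
            self._compute_sources(kappa + 1, suffix="__old")
            model.compute_face_velocities(h, kappa + 1, prm, suffix="__old")
            build_ch_rhs(h, kappa + 1, prm, cfg, suffix="__old")
            return True

        return hook

    # -- driver -------------------------------------------------------------
    def run(self):
        spec = self.spec
        outputs = []
        while self.step_index < spec.n_steps:
            self.step()
            if (spec.out_dir and spec.output_every
                    and self.step_index % spec.output_every == 0):
                outputs += self.write_output(
                    label=f"_t{self.step_index:05d}")
        if spec.out_dir:
            outputs += self.write_output(label="_final")
        return outputs

    def write_output(self, label=""):
        return write_output(self, self.spec.out_dir, label=label)


def _pad_edge(arr):
    nd = arr.ndim
    for a in range(nd):
        g = [slice(None)] * nd
        i = [slice(None)] * nd
        g[a], i[a] = 0, 1
        arr[tuple(g)] = arr[tuple(i)]
        g[a], i[a] = -1, -2
        arr[tuple(g)] = arr[tuple(i)]
    return arr


def _clip_to_parent(bl: adapt.BlockList, parent_level) -> adapt.BlockList:
    """Intersect generated fine boxes with the parent level's (doubled)
    block union so proper nesting holds even across parent block gaps."""
    out = adapt.BlockList(bl.kappa, [])
    for lo, hi in bl.boxes:
        for pb in parent_level.blocks:
            plo = tuple(2 * l - 1 for l in pb.lo)
            phi_ = tuple(2 * x for x in pb.hi)
            olo = tuple(max(a, c) for a, c in zip(lo, plo))
            ohi = tuple(min(a, c) for a, c in zip(hi, phi_))
            if all(a <= c for a, c in zip(olo, ohi)):
                out.boxes.append((olo, ohi))
    return out


# ---------------------------------------------------------------------------
# initial condition
# ---------------------------------------------------------------------------

def initial_condition(spec: RunSpec) -> MeshHierarchy:
    """Seeded initial state on the global levels.

    A cubic viable-cell seed (phi_V = seed_phiV, sharp interface) sits at
    the domain center; the ECM is uniform (phi_E = phiE0); healthy cells
    fill the rest of the solid phase; nutrients start at their boundary
    values and vessels at their far fields.  The quasi-steady species and
    the chemical potentials are then solved/evaluated once so the first
    step has a consistent old-time state.
    """
    prm = spec.params
    h = build_hierarchy(spec.domain, spec.root_cells, spec.n_coarse_global,
                        spec.kappa_max)
    state = spec.state_fields
    nd = h.ndim
    for kappa in range(h.kappa_min, 1):
        lev = h.level(kappa)
        for b in lev.blocks:
            b.alloc(state)
            centers = []
            for a in range(nd):
                L, R = h.domain[a]
                i = np.arange(b.lo[a] - 1, b.hi[a] + 2, dtype=float)
                centers.append(L + (i - 0.5) * lev.eta)
            grids = np.meshgrid(*centers, indexing="ij")
            inside = np.ones_like(grids[0], dtype=bool)
            for a in range(nd):
                L, R = h.domain[a]
                c = 0.5 * (L + R)
                inside &= np.abs(grids[a] - c) < 0.5 * prm.seed_side
            f = b.data
            f["phi_V"][...] = np.where(inside, prm.seed_phiV, 0.0)
            f["phi_D"][...] = 0.0
            f["phi_E"][...] = prm.phiE0
            f["n"][...] = 1.0
            f["g"][...] = 1.0
            f["F_E"][...] = prm.FE0
            f["B_nE"][...] = prm.B_inf
            f["L_nE"][...] = prm.L_inf
            # tgf, taf, m, p (and ions) start at zero
        tr.fill_level_ghosts(h, kappa, model.bc_table(prm))
        model.chemical_potentials(h, kappa, prm)
        tr.fill_level_ghosts(h, kappa, model.bc_table(prm))
    cfg = spec.solver
    model.quasi_steady_species_system(h, prm, cfg,
                                      with_ions=(spec.profile == "full"),
                                      tol=cfg.tol_min)
    return h


def run_simulation(spec: RunSpec) -> Simulation:
    """Run the configured simulation to its end time; returns the driver
    (with hierarchy, logs, and any written outputs)."""
    sim = Simulation(spec)
    sim.run()
    return sim


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_output(sim: Simulation, out_dir, label="") -> list:
    """VTK per-block files, an HDF5 checkpoint, CSV logs, and the mesh
    summary JSON."""
    os.makedirs(out_dir, exist_ok=True)
    h = sim.h
    # derived fields for inspection
    for lev in h.levels:
        for b in lev.blocks:
            b.data["phi_T"] = b.data["phi_V"] + b.data["phi_D"]
            b.data["phi_H"] = model.phi_H_of(b.data)
    fields = sim.spec.state_fields + ["phi_T", "phi_H"]
    paths = io.write_vtk(h, os.path.join(out_dir, "fields"), fields, label)
    ck = os.path.join(out_dir, f"checkpoint{label}.h5")
    io.write_checkpoint(h, ck, config_echo={
        "theta": sim.cfg.theta, "t": sim.t, "step": sim.step_index,
        "profile": sim.spec.profile})
    paths.append(ck)
    io.write_csv_log(sim.cycle_log, os.path.join(out_dir, "residuals.csv"))
    io.write_csv_log(sim.dof_log, os.path.join(out_dir, "dof.csv"))
    import json
    with open(os.path.join(out_dir, f"mesh{label}.json"), "w") as f:
        json.dump(mesh_summary(h), f, indent=2)
    return paths


# ---------------------------------------------------------------------------
# convergence study
# ---------------------------------------------------------------------------

def composite_uniform(h: MeshHierarchy, name: str, kappa_target: int,
                      sync_first: bool = False) -> np.ndarray:
    """Composite field on the uniform grid of level ``kappa_target``:
    coarser data is linearly interpolated upward and overwritten by actual
    fine-level data wherever refined blocks exist."""
    root = h.level(0)
    arr = tr.gather_patch(root, (1,) * h.ndim, h.ncells_axis(0), name)
    for k in range(1, kappa_target + 1):
        pad = np.zeros(tuple(n + 2 for n in arr.shape))
        pad[(slice(1, -1),) * h.ndim] = arr
        _pad_edge(pad)
        arr = tr.prolong_linear(pad)
        if k <= h.kappa_max and h.level(k).blocks:
            for b in h.level(k).blocks:
                if name in b.data:
                    sl = tuple(slice(l - 1, x) for l, x in zip(b.lo, b.hi))
                    arr[sl] = b.interior(name)
    return arr


def convergence_study(root_sizes, kappa_max: int, end_time: float,
                      spec: RunSpec | None = None,
                      theta_coeff: float = 0.032) -> dict:
    """Space-time refinement study along the linear path theta = 0.032 eta.

    Runs the simulation at each root resolution (sizes in ratio 2), with
    the time step tied to the finest spacing eta_{kappa_max} (adjusted
    minimally so each run ends exactly at ``end_time``).  The total tumor
    fraction is composited onto each run's uniform eta_{kappa_max} grid,
    successive runs are compared after averaging the finer result down, and
    convergence rates are log2 ratios of the successive l2 errors.
    """
    root_sizes = list(root_sizes)
    for a, b in zip(root_sizes, root_sizes[1:]):
        if b != 2 * a:
            raise ValueError("root sizes must double")
    base = spec if spec is not None else RunSpec()
    fields = []
    thetas = []
    dofs = []
    for n in root_sizes:
        sp = copy.deepcopy(base)
        sp.root_cells = (n,) * len(base.domain)
        sp.kappa_max = kappa_max
        eta_fine = (base.domain[0][1] - base.domain[0][0]) / (n * 2**kappa_max)
        theta0 = theta_coeff * eta_fine
        n_steps = max(1, round(end_time / theta0))
        sp.solver = copy.deepcopy(base.solver)
        sp.solver.theta = end_time / n_steps
        sp.end_time = end_time
        sp.__post_init__()
        sim = run_simulation(sp)
        for k in sim._active():
            for b in sim.h.level(k).blocks:
                b.data["phi_T"] = b.data["phi_V"] + b.data["phi_D"]
        fields.append(composite_uniform(sim.h, "phi_T", kappa_max))
        thetas.append(sp.solver.theta)
        dofs.append(count_dof(sim.h))
    errors, rates = grid_errors(fields)
    return {"root_sizes": root_sizes, "thetas": thetas, "errors": errors,
            "rates": rates, "dofs": dofs}


def grid_errors(fields):
    """Successive-grid l2 errors (finer field averaged down to the coarser
    grid) and log2 convergence rates."""
    errors = []
    for coarse, fine in zip(fields, fields[1:]):
        diff = tr.restrict_avg(fine) - coarse
        errors.append(float(np.sqrt((diff**2).mean())))
    rates = [float(np.log2(e1 / e2)) for e1, e2 in zip(errors, errors[1:])]
    return errors, rates


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def fixture_generators(name: str, n: int = 16, n_global: int = 3,
                       theta: float = 1e-3):
    """Manufactured validation problems.

    * ``poisson_mms``: -lap(u) = f with u = prod(sin(pi x_a)) on (0,1)^3
      (returns hierarchy, system, and the analytic solution on the root);
    * ``heat_mms``: one Crank-Nicolson heat step from random data (returns
      hierarchy, system, and the dense-oracle ingredients);
    * ``cahn_hilliard_scalar``: smooth initial data for the conservative
      scalar Cahn-Hilliard fixture (returns hierarchy, system);
    * ``tumor``: the seeded tumor RunSpec with reference defaults.
    """
    from .solver import CahnHilliardScalarSystem

    if name == "poisson_mms":
        h = build_hierarchy([(0.0, 1.0)] * 3, (n,) * 3, n_global, 0)
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        for kappa in h.kappas():
            lev = h.level(kappa)
            for b in lev.blocks:
                b.alloc(["u", "coef_a_u", "coef_d_u", "rhs_u"])
                b.data["coef_d_u"][...] = 1.0
                x = [(np.arange(l, hi + 1) - 0.5) * lev.eta
                     for l, hi in zip(b.lo, b.hi)]
                X, Y, Z = np.meshgrid(*x, indexing="ij")
                u = np.sin(np.pi * X) * np.sin(np.pi * Y) * np.sin(np.pi * Z)
                b.interior("rhs_u")[...] = 3 * np.pi**2 * u
                if kappa == 0:
                    exact = u
            tr.fill_level_ghosts(h, kappa, sys_.bc_map())
        return h, sys_, exact
    if name == "heat_mms":
        h = build_hierarchy([(0.0, 1.0)] * 3, (n,) * 3, n_global, 0)
        sys_ = ScalarLinearSystem("u", ("dirichlet", 0.0))
        rng = np.random.default_rng(0)
        for kappa in h.kappas():
            lev = h.level(kappa)
            for b in lev.blocks:
                b.alloc(["u", "coef_a_u", "coef_d_u", "rhs_u"])
                b.data["coef_a_u"][...] = 1.0 / theta
                b.data["coef_d_u"][...] = 0.5
            tr.fill_level_ghosts(h, kappa, sys_.bc_map())
        b = h.level(0).blocks[0]
        u0 = rng.normal(size=b.shape)
        b.interior("u")[...] = u0
        tr.fill_level_ghosts(h, 0, sys_.bc_map())
        b.interior("rhs_u")[...] = (u0 / theta
                                    + 0.5 * st.laplacian(b.data["u"],
                                                         h.level(0).eta))
        return h, sys_, u0
    if name == "cahn_hilliard_scalar":
        h = build_hierarchy([(0.0, 1.0)] * 3, (n,) * 3, n_global, 0)
        sys_ = CahnHilliardScalarSystem(theta=theta, eps=0.1, A=1.0)
        for kappa in h.kappas():
            h.level(kappa).alloc(["phi", "mu", "rhs_phi", "rhs_mu"])
        b = h.level(0).blocks[0]
        x = (np.arange(n) + 0.5) / n
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        b.interior("phi")[...] = (0.5 + 0.2 * np.cos(2 * np.pi * X)
                                  * np.cos(2 * np.pi * Y) * np.cos(np.pi * Z))
        for k in range(0, h.kappa_min, -1):
            tr.restrict_level_to_coarse(h, k, ["phi"])
        return h, sys_
    if name == "tumor":
        return RunSpec()
    raise ValueError(f"unknown fixture {name!r}")
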