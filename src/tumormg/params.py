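"""Model parameters for the multispecies desmoplastic tumor model.

Every rate constant, energy coefficient, diffusivity, and threshold of the
model lives here with a documented default.  Two provenance classes exist:

* ``main``: values printed in the model's primary description (source-term
  rate constants, viability thresholds, far-field vessel densities, the
  seed composition);
* ``placeholder``: order-one defaults standing in for the supplementary
  parameterization that is not part of this package's scope.  These are all
  configurable and are flagged in the shipped reference config.

Diffusivities and vascular mass-transfer coefficients are *tissue-effective*
quantities: each is specified as a triple ``(psi_E, psi_T, psi_H)`` of values
in the ECM, tumor, and healthy-host domains, blended pointwise with the
interpolation function Q3 (see :func:`tumormg.model.effective_coefficient`).
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields, asdict

import yaml

__all__ = ["ModelParams", "PROVENANCE"]

Triple = tuple  # (psi_E, psi_T, psi_H)


@dataclass
class ModelParams:
    # --- bulk free energy (ternary semi-immiscible form) ------------------
    A1: float = 1.0
    A2: float = 0.0
    A3: float = 0.0
    A4: float = 0.0
    A5: float = 0.0
    # interface / elastic energy coefficients
    eps_T: float = 1.0
    eps_E: float = 1.0
    eps_TE: float = 0.5
    eps_e: float = 0.0          # elastic energy off by default
    # --- mechanics --------------------------------------------------------
    Mbar: float = 1.0           # mobility scale, M_i = Mbar * phi_i
    k_alpha: float = 1.0        # solid (cell-ECM) phase motility
    k_beta: float = 1.0         # liquid phase motility
    R_alphabeta: float = 1.0    # interphase resistance ratio in the q solve
    gamma_T: float = 1.0
    gamma_E: float = 1.0
    # Lame constants and eigenstrains (elasticity; supplement placeholders)
    L1E: float = 1.0
    L2E: float = 1.0
    L1C: float = 1.0
    L2C: float = 1.0
    Estar_E: float = 0.01
    Estar_C: float = 0.0
    # --- charged species --------------------------------------------------
    z_l: int = -1               # lactate
    z_b: int = -1               # bicarbonate
    z_a: int = 1                # H+
    z_s: int = 1                # Na+
    z_r: int = -1               # Cl-
    drift_eps: float = 1e-12    # guard for the electro-diffusive denominator
    # --- effective diffusivity triples (psi_E, psi_T, psi_H) --------------
    D_n: Triple = (1.0, 1.0, 1.0)
    D_g: Triple = (1.0, 1.0, 1.0)
    D_w: Triple = (1.0, 1.0, 1.0)
    D_l: Triple = (1.0, 1.0, 1.0)
    D_b: Triple = (1.0, 1.0, 1.0)
    D_a: Triple = (1.0, 1.0, 1.0)
    D_s: Triple = (1.0, 1.0, 1.0)
    D_tgf: Triple = (1.0, 1.0, 1.0)
    D_taf: Triple = (1.0, 1.0, 1.0)
    D_m: Triple = (1.0, 1.0, 1.0)
    D_F: float = 0.1            # chemotactic mobility of myofibroblasts
    D_BnE: float = 0.1
    D_LnE: float = 0.1
    # --- vascular supply (mass transfer) and uptake rates ------------------
    lam_B_n: Triple = (1.0, 1.0, 1.0)    # k_n1 blend
    lam_B_g: Triple = (1.0, 1.0, 1.0)    # k_g1 blend
    lam_B_w: Triple = (1.0, 1.0, 1.0)    # k_w blend
    lam_B_l: Triple = (1.0, 1.0, 1.0)    # k_l blend
    k_n2: Triple = (0.05, 1.0, 0.05)     # O2 uptake, tumor-weighted
    k_g2: Triple = (0.05, 1.0, 0.05)     # glucose uptake
    k_f: float = 1.0            # CO2 + H2O -> HCO3- + H+ forward rate
    k_r: float = 1.0            # reverse rate
    R_gn: float = 1.0           # glycolysis/respiration stoichiometry ratio
    # --- tumorigenic species rates -----------------------------------------
    lam_pro_tgf: float = 1.0    # secretion by viable tumor cells
    lam_de_tgf: float = 1.0
    lam_U_tgf: float = 0.0
    lam_pro_taf: float = 1.0
    lam_de_taf: float = 0.1
    lam_U_taf: float = 1.0      # uptake per unit vessel density
    lam_pro_m: float = 1.0
    lam_de_m: float = 1.0
    # chemo/haptotaxis coefficients and adjustment factors for vessels
    chi_che_B: float = 0.1
    chi_hap_B: float = 0.1
    chi_che_L: float = 0.1
    chi_hap_L: float = 0.1
    A_che: float = 1.0
    A_hap: float = 1.0
    # --- printed source-term constants -------------------------------------
    lam_MV: float = 1.0         # mitosis rate of viable cells
    lam_NV: float = 3.0         # necrosis rate of viable cells
    lam_LD: float = 1.0         # lysis rate of dead cells
    lam_FE: float = 5.0         # ECM secretion by myofibroblasts
    lam_deE: float = 5.0        # ECM degradation by MDEs
    F_nEF: float = 2.0          # hypoxic upregulation of ECM production
    n_h: float = 0.3            # hypoxic oxygen level
    n_vV: float = 0.21          # oxygen viability limit, viable tumor cells
    g_vV: float = 0.1           # glucose viability limit
    n_vF: float = 0.21          # oxygen viability limit, myofibroblasts
    tgf_FE: float = 0.2         # TGF threshold for ECM production
    # --- myofibroblast / vessel remodeling (placeholders) ------------------
    lam_pro_F: float = 1.0
    lam_apo_F: float = 0.1
    lam_N_F: float = 1.0
    lam_sp_B: float = 1.0       # sprouting rate scale, blood vessels
    lam_cr_B: float = 1.0       # pressure-crushing loss rate
    lam_sp_L: float = 1.0
    lam_cr_L: float = 1.0
    # per-octant sprouting fractions (slight symmetry perturbation)
    sprout_fractions: tuple = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    # --- far fields and initial composition --------------------------------
    B_inf: float = 0.2
    L_inf: float = 0.2
    seed_phiV: float = 0.65
    seed_side: float = 10.0
    phiE0: float = 0.35
    FE0: float = 0.1
    # numerical guards
    phiC_eps: float = 1e-12

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        kwargs = {}
        valid = {f.name for f in dc_fields(cls)}
        for k, v in d.items():
            if k not in valid:
                raise KeyError(f"unknown model parameter {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def dump_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "ModelParams":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


#: provenance tag per parameter: printed main-text value vs. documented
#: paper-supplement placeholder (order-one default, configurable).
PROVENANCE: dict[str, str] = {
    name: "placeholder" for name in (
        "A1", "A2", "A3", "A4", "A5", "eps_T", "eps_E", "eps_TE", "eps_e",
        "Mbar", "k_alpha", "k_beta", "R_alphabeta", "gamma_T", "gamma_E",
        "L1E", "L2E", "L1C", "L2C", "Estar_E", "Estar_C",
        "D_n", "D_g", "D_w", "D_l", "D_b", "D_a", "D_s", "D_tgf", "D_taf",
        "D_m", "D_F", "D_BnE", "D_LnE",
        "lam_B_n", "lam_B_g", "lam_B_w", "lam_B_l", "k_n2", "k_g2",
        "k_f", "k_r", "R_gn",
        "lam_pro_tgf", "lam_de_tgf", "lam_U_tgf", "lam_pro_taf",
        "lam_de_taf", "lam_U_taf", "lam_pro_m", "lam_de_m",
        "lam_pro_F", "lam_apo_F", "lam_N_F",
        "chi_che_B", "chi_hap_B", "chi_che_L", "chi_hap_L", "A_che", "A_hap",
        "lam_sp_B", "lam_cr_B", "lam_sp_L", "lam_cr_L", "sprout_fractions",
        "FE0", "drift_eps", "phiC_eps",
    )
}
PROVENANCE.update({name: "main" for name in (
    "z_l", "z_b", "z_a", "z_s", "z_r",
    "lam_MV", "lam_NV", "lam_LD", "lam_FE", "lam_deE", "F_nEF",
    "n_h", "n_vV", "g_vV", "n_vF", "tgf_FE", "B_inf", "L_inf",
    "seed_phiV", "seed_side", "phiE0",
)})


def write_reference_config(path) -> None:
    """Write the shipped reference config with per-parameter provenance."""
    p = ModelParams()
    lines = ["# Reference model configuration.",
             "# 'main' = printed model constant; 'placeholder' = documented",
             "# order-one default standing in for the supplementary tables.",
             ""]
    for f in dc_fields(ModelParams):
        v = getattr(p, f.name)
        if isinstance(v, tuple):
            v = list(v)
        tag = PROVENANCE.get(f.name, "placeholder")
        lines.append(f"{f.name}: {v}    # {tag}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
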