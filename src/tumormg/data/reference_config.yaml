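# Reference model configuration.
# 'main' = printed model constant; 'placeholder' = documented
# order-one default standing in for the supplementary tables.

A1: 1.0    # placeholder
A2: 0.0    # placeholder
A3: 0.0    # placeholder
A4: 0.0    # placeholder
A5: 0.0    # placeholder
eps_T: 1.0    # placeholder
eps_E: 1.0    # placeholder
eps_TE: 0.5    # placeholder
eps_e: 0.0    # placeholder
Mbar: 1.0    # placeholder
k_alpha: 1.0    # placeholder
k_beta: 1.0    # placeholder
R_alphabeta: 1.0    # placeholder
gamma_T: 1.0    # placeholder
gamma_E: 1.0    # placeholder
L1E: 1.0    # placeholder
L2E: 1.0    # placeholder
L1C: 1.0    # placeholder
L2C: 1.0    # placeholder
Estar_E: 0.01    # placeholder
Estar_C: 0.0    # placeholder
z_l: -1    # main
z_b: -1    # main
z_a: 1    # main
z_s: 1    # main
z_r: -1    # main
drift_eps: 1e-12    # placeholder
D_n: [1.0, 1.0, 1.0]    # placeholder
D_g: [1.0, 1.0, 1.0]    # placeholder
D_w: [1.0, 1.0, 1.0]    # placeholder
D_l: [1.0, 1.0, 1.0]    # placeholder
D_b: [1.0, 1.0, 1.0]    # placeholder
D_a: [1.0, 1.0, 1.0]    # placeholder
D_s: [1.0, 1.0, 1.0]    # placeholder
D_tgf: [1.0, 1.0, 1.0]    # placeholder
D_taf: [1.0, 1.0, 1.0]    # placeholder
D_m: [1.0, 1.0, 1.0]    # placeholder
D_F: 0.1    # placeholder
D_BnE: 0.1    # placeholder
D_LnE: 0.1    # placeholder
lam_B_n: [1.0, 1.0, 1.0]    # placeholder
lam_B_g: [1.0, 1.0, 1.0]    # placeholder
lam_B_w: [1.0, 1.0, 1.0]    # placeholder
lam_B_l: [1.0, 1.0, 1.0]    # placeholder
k_n2: [0.05, 1.0, 0.05]    # placeholder
k_g2: [0.05, 1.0, 0.05]    # placeholder
k_f: 1.0    # placeholder
k_r: 1.0    # placeholder
R_gn: 1.0    # placeholder
lam_pro_tgf: 1.0    # placeholder
lam_de_tgf: 1.0    # placeholder
lam_U_tgf: 0.0    # placeholder
lam_pro_taf: 1.0    # placeholder
lam_de_taf: 0.1    # placeholder
lam_U_taf: 1.0    # placeholder
lam_pro_m: 1.0    # placeholder
lam_de_m: 1.0    # placeholder
chi_che_B: 0.1    # placeholder
chi_hap_B: 0.1    # placeholder
chi_che_L: 0.1    # placeholder
chi_hap_L: 0.1    # placeholder
A_che: 1.0    # placeholder
A_hap: 1.0    # placeholder
lam_MV: 1.0    # main
lam_NV: 3.0    # main
lam_LD: 1.0    # main
lam_FE: 5.0    # main
lam_deE: 5.0    # main
F_nEF: 2.0    # main
n_h: 0.3    # main
n_vV: 0.21    # main
g_vV: 0.1    # main
n_vF: 0.21    # main
tgf_FE: 0.2    # main
lam_pro_F: 1.0    # placeholder
lam_apo_F: 0.1    # placeholder
lam_N_F: 1.0    # placeholder
lam_sp_B: 1.0    # placeholder
lam_cr_B: 1.0    # placeholder
lam_sp_L: 1.0    # placeholder
lam_cr_L: 1.0    # placeholder
sprout_fractions: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]    # placeholder
B_inf: 0.2    # main
L_inf: 0.2    # main
seed_phiV: 0.65    # main
seed_side: 10.0    # main
phiE0: 0.35    # main
FE0: 0.1    # placeholder
phiC_eps: 1e-12    # placeholder
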