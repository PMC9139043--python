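# Canonical p-type Si / SiO2 EISCAP used throughout the simulation study:
# C-V curves for five nanoparticle coverages at delta_phi = +40 mV
# (phi_NP = +30 mV against phi_0 = -10 mV).
device:
  eps_ir: 3.9          # SiO2
  d_i_nm: 35
  eps_sr: 11.7         # Si
  N_a_per_cm3: 2.76e+15 # ~5 Ohm*cm p-type wafer
  n_i_per_cm3: 1.5e+10
  T_K: 300
  A_cm2: 0.5
  V_ip_mV: 0
  phi_0_mV: -10
layer:
  n: 0.25
  delta_phi_mV: 40     # phi_NP - phi_0 for positively charged particles
run:
  mode: cv
  V_min_mV: -500
  V_max_mV: 1500
  n_points: 2001       # 1 mV grid
  coverages: [0.0, 0.25, 0.5, 0.75, 0.9]
  output_dir: out_cv
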