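# Synthetic hard-disk particle field: 28 nm particles placed by random
# sequential adsorption to the highest coverage reached experimentally
# after 2 h of immobilization (n = 0.36).
device:
  eps_ir: 3.9
  d_i_nm: 35
  eps_sr: 11.7
  N_a_per_cm3: 2.76e+15
  n_i_per_cm3: 1.5e+10
  T_K: 300
  A_cm2: 0.5
  V_ip_mV: 0
  phi_0_mV: -10
run:
  mode: particles
  patch_width_um: 1.0
  patch_height_um: 1.0
  target_coverage: 0.36
  diameter_nm: 28
  seed: 42
  output_dir: out_particles
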