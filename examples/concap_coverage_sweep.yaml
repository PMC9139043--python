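# ConCap signal change versus nanoparticle coverage at the 30 nF working
# capacitance (baseline gate voltage ~50 mV) of the canonical device.
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
layer:
  n: 0.25
  delta_phi_mV: 40
run:
  mode: sweep
  C_work_nF: 30
  coverages: [0.25, 0.5, 0.75, 0.9]
  output_dir: out_sweep
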