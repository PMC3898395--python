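# Reference run configuration: the measurement design the package emulates.
# Drain sweep 0-0.7 V (71 points); buffer at 1 mg/mL shifting the gate by
# 0.6 V; glucose stepped 0-50 mM with the default piecewise-exponential law.
device:
  cnt_diameter_nm: 1.5
  channel_length_um: 50
  substrate_thickness_um: 100
  relative_permittivity: 3.3
transport:
  mobility_m2_per_Vs: 0.1
  saturation_velocity_m_per_s: 8.0e5
  fermi_velocity_m_per_s: 1.0e6
  threshold_voltage_V: 0.3
sensing:
  v_gs_bare_V: 1.5
  pbs_concentration_mg_per_mL: 1.0
  pbs_voltage_V: 0.6
  glucose_concentrations_mM: [0, 2, 4, 6, 8, 10, 20, 50]
  law_asymptote_V: 1.42
  law_rate_per_mM: 0.1
sweep:
  v_d_start_V: 0.0
  v_d_stop_V: 0.7
  n_points: 71
noise:
  multiplicative_sd: 0.01
  additive_sd_uA: 0.0
  seed: 1
fit:
  free_parameters: [v_pbs, law_asymptote, law_rate]
  max_iterations: 200
  tolerance: 1.0e-12
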