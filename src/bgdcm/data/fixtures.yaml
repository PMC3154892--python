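# Calibrated ground-truth regimes for the synthetic cohort.
#
# Log-scale deviations from the circuit prior means.  The shared base
# places the circuit near the operating point needed for both regimes: a
# fast, moderately strong cortical pyramidal-interneuron loop supplying a
# ~50 Hz (unit-circle reading) gamma resonance; quickened striatal and
# pallidal kinetics with strong corticostriatal and striatopallidal gains
# so the indirect pathway participates in the beta mode; and an excitable
# long loop cortex -> STN -> EPN -> thalamus -> cortex whose gain rides on
# the hyperdirect connection.  The parkinsonian regime differs from
# control ONLY in a strengthened hyperdirect (cortex->STN) connection and
# a weakened STN->GPe connection; noise levels are identical.
# Calibration targets: parkinsonian channel-averaged spectrum peaks at
# 17 Hz on the 10-35 Hz grid and exceeds control at 16-18 Hz on every
# channel; control is broadband in 10-35 Hz with its dominant supra-30 Hz
# pole reading ~50 Hz on the unit circle.
version: "1"
base_deviations:
  kappa_ctx_ii: 2.1
  H_ctx_ii: 2.1
  delay_intrinsic: -1.2
  g_ctx_py_ctx_ii: 0.8
  g_ctx_ii_ctx_py: 0.8
  c_stn_epn: 0.8
  c_epn_tha: 0.8
  c_tha_ctx: 0.8
  c_ctx_stn: 1.2
  kappa_epn: 0.05
  H_epn: 0.05
  c_ctx_str: 1.5
  c_str_gpe: 1.2
  kappa_str: 0.9
  H_str: 0.9
  kappa_gpe: 0.9
  H_gpe: 0.9
  u_scale_str: -1.5
  u_scale_gpe: -1.5
regimes:
  control:
    target_beta_hz: 17
    gamma_pole_hz: 50
    deviations: {}
  parkinsonian:
    target_beta_hz: 17
    gamma_pole_hz: 50
    deviations:
      c_ctx_stn: 2.6
      c_stn_gpe: -0.8
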