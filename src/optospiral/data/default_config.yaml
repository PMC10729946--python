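# Frozen default calibration of the optospiral monodomain model.
# Tissue geometry and coupling reproduce the standard murine-sheet setup:
# 100 x 100 nodes at 0.25 mm, D = 0.00014 cm^2/ms (plane-wave CV 43.9 cm/s),
# C_m = 1.0 uF/cm^2.  The membrane calibration yields a stable single spiral
# (~35 Hz, sub-millimetre core) and a 500-ms single-cell optical threshold
# between 20 and 25 uW/mm^2.
tissue:
  nx: 100
  ny: 100
  dx: 0.025          # cm
  d_coeff: 0.00014   # cm^2/ms
  c_m: 1.0           # uF/cm^2
  dt: 0.01           # ms
ionic:
  v_rest: -80.0      # mV
  v_amp: 120.0       # mV
  u_c: 0.065
  u_v: 0.04
  u_csi: 2.0         # slow-inward suppressed (murine calibration)
  k_si: 10.0
  tau_d: 0.004       # ms
  tau_v_plus: 1.5    # ms
  tau_v1_minus: 10.0 # ms
  tau_v2_minus: 10.0 # ms
  tau_w_plus: 10.0   # ms
  tau_w_minus: 40.0  # ms
  tau_0: 0.1         # ms
  tau_r: 8.0         # ms
  tau_si: 20.0       # ms
  c_m: 1.0           # uF/cm^2
  u_h: 0.025
  k_h: 0.015
  q_vc: 0.12
  u_k: 0.04
  leak_act: 0.7
chr2:
  g_chr2: 0.6503     # mS/cm^2, calibrated (500-ms threshold 23.7 uW/mm^2)
  gamma: 0.1
  e_chr2: 0.0        # mV, fixed
  k_a1: 0.8          # per ms per mW/mm^2
  k_a2: 0.2          # per ms per mW/mm^2
  g_d1: 0.10         # per ms
  g_d2: 0.05         # per ms
  g_r: 0.00033       # per ms
  e_12: 0.053        # per ms
  e_21: 0.023        # per ms
analysis:
  v_threshold: -50.0      # mV, binarization before Canny
  v_iso: -50.0            # mV, tip-tracking isopotential
  canny_sigma: 1.0        # nodes
  hough_radius_range: [2, 45]   # nodes
  peak_prominence: 20.0   # mV
  peak_min_separation: 10.0     # ms
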