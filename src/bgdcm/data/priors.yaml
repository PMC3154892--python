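# Versioned priors table for the standard circuit: log-scale Gaussian
# priors; prior_mean is the physical value at zero log-deviation.
version: '1'
classes:
  connectivity: 0.33136863190489996
  synaptic: 0.12011325347955035
  noise: 0.5
  gain: 0.0625
  delay: 0.0625
parameters:
- name: H_ctx_ss
  prior_mean: 8.0
  class: synaptic
  prior_variance: 0.12011325347955035
- name: H_ctx_py
  prior_mean: 8.0
  class: synaptic
  prior_variance: 0.12011325347955035
- name: H_ctx_ii
  prior_mean: 32.0
  class: synaptic
  prior_variance: 0.12011325347955035
- name: H_str
  prior_mean: 32.0
  class: synaptic
  prior_variance: 0.12011325347955035
- name: H_gpe
  prior_mean: 32.0
  class: synaptic
  prior_variance: 0.12011325347955035
- name: H_stn
  prior_mean: 8.0
  class: synaptic
  prior_variance: 0.12011325347955035
- name: H_epn
  prior_mean: 32.0
  class: synaptic
  prior_variance: 0.12011325347955035
- name: H_tha
  prior_mean: 8.0
  class: synaptic
  prior_variance: 0.12011325347955035
- name: kappa_ctx_ss
  prior_mean: 0.25
  class: synaptic
  prior_variance: 0.12011325347955035
- name: kappa_ctx_py
  prior_mean: 0.25
  class: synaptic
  prior_variance: 0.12011325347955035
- name: kappa_ctx_ii
  prior_mean: 0.0625
  class: synaptic
  prior_variance: 0.12011325347955035
- name: kappa_str
  prior_mean: 0.0625
  class: synaptic
  prior_variance: 0.12011325347955035
- name: kappa_gpe
  prior_mean: 0.0625
  class: synaptic
  prior_variance: 0.12011325347955035
- name: kappa_stn
  prior_mean: 0.25
  class: synaptic
  prior_variance: 0.12011325347955035
- name: kappa_epn
  prior_mean: 0.0625
  class: synaptic
  prior_variance: 0.12011325347955035
- name: kappa_tha
  prior_mean: 0.25
  class: synaptic
  prior_variance: 0.12011325347955035
- name: rho
  prior_mean: 0.56
  class: synaptic
  prior_variance: 0.12011325347955035
- name: g_ctx_py_ctx_ss
  prior_mean: 1.376068131169081
  class: connectivity
  prior_variance: 0.33136863190489996
- name: g_ctx_ss_ctx_py
  prior_mean: 1.376068131169081
  class: connectivity
  prior_variance: 0.33136863190489996
- name: g_ctx_py_ctx_ii
  prior_mean: 0.08600425819806756
  class: connectivity
  prior_variance: 0.33136863190489996
- name: g_ctx_ii_ctx_py
  prior_mean: 1.376068131169081
  class: connectivity
  prior_variance: 0.33136863190489996
- name: c_ctx_str
  prior_mean: 0.06450319364855067
  class: connectivity
  prior_variance: 0.33136863190489996
- name: c_ctx_stn
  prior_mean: 1.0320510983768107
  class: connectivity
  prior_variance: 0.33136863190489996
- name: c_str_gpe
  prior_mean: 0.06450319364855067
  class: connectivity
  prior_variance: 0.33136863190489996
- name: c_str_epn
  prior_mean: 0.06450319364855067
  class: connectivity
  prior_variance: 0.33136863190489996
- name: c_gpe_stn
  prior_mean: 1.0320510983768107
  class: connectivity
  prior_variance: 0.33136863190489996
- name: c_stn_gpe
  prior_mean: 0.06450319364855067
  class: connectivity
  prior_variance: 0.33136863190489996
- name: c_stn_epn
  prior_mean: 0.06450319364855067
  class: connectivity
  prior_variance: 0.33136863190489996
- name: c_epn_tha
  prior_mean: 1.0320510983768107
  class: connectivity
  prior_variance: 0.33136863190489996
- name: c_tha_ctx
  prior_mean: 1.0320510983768107
  class: connectivity
  prior_variance: 0.33136863190489996
- name: delay_intrinsic
  prior_mean: 1.0
  class: delay
  prior_variance: 0.0625
- name: delay_extrinsic
  prior_mean: 1.0
  class: delay
  prior_variance: 0.0625
- name: u_white
  prior_mean: 0.05
  class: noise
  prior_variance: 0.5
- name: u_pink
  prior_mean: 0.5
  class: noise
  prior_variance: 0.5
- name: u_scale_ctx_ss
  prior_mean: 1.0
  class: noise
  prior_variance: 0.5
- name: u_scale_str
  prior_mean: 1.0
  class: noise
  prior_variance: 0.5
- name: u_scale_gpe
  prior_mean: 1.0
  class: noise
  prior_variance: 0.5
- name: u_scale_stn
  prior_mean: 1.0
  class: noise
  prior_variance: 0.5
- name: u_scale_tha
  prior_mean: 1.0
  class: noise
  prior_variance: 0.5
- name: n_ctx_white
  prior_mean: 0.002
  class: noise
  prior_variance: 0.5
- name: n_ctx_pink
  prior_mean: 0.02
  class: noise
  prior_variance: 0.5
- name: n_bg_white
  prior_mean: 0.002
  class: noise
  prior_variance: 0.5
- name: n_bg_pink
  prior_mean: 0.02
  class: noise
  prior_variance: 0.5
- name: n_bgc_white
  prior_mean: 0.001
  class: noise
  prior_variance: 0.5
- name: n_bgc_pink
  prior_mean: 0.01
  class: noise
  prior_variance: 0.5
- name: gain_ctx
  prior_mean: 1.0
  class: gain
  prior_variance: 0.0625
- name: gain_str
  prior_mean: 1.0
  class: gain
  prior_variance: 0.0625
- name: gain_gpe
  prior_mean: 1.0
  class: gain
  prior_variance: 0.0625
- name: gain_stn
  prior_mean: 1.0
  class: gain
  prior_variance: 0.0625
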