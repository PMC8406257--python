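# Delta tnaA supplemented with 0.5 mM extracellular indole during overnight
# growth (persistent indole signalling mimic). Persister fraction collapses
# to 0.001; VBNC fraction is unaffected. All fates start more alkaline than
# the plain knockout (~7.6); VBNC/susceptible cells drop steeply by >0.5 pH
# units on treatment, to a minimum of 7.0; persisters show no significant
# change throughout.
name: delta_tnaA_indole_0.5mM
fate_probs: [0.001, 0.04, 0.959]
susceptible_lysed_fraction: 0.9
t0_ph_dist:
  persister:
    means: [7.6]
    sds: [0.15]
    weights: [1.0]
  vbnc:
    means: [7.6]
    sds: [0.15]
    weights: [1.0]
  susceptible:
    means: [7.6]
    sds: [0.15]
    weights: [1.0]
trajectory_anchors:
  persister:
    - [0.0, 7.6]
    - [24.0, 7.6]
  vbnc:
    - [0.0, 7.6]
    - [1.0, 7.4]
    - [2.0, 7.15]
    - [3.0, 7.0]
    - [6.0, 7.0]
    - [24.0, 7.0]
  susceptible:
    - [0.0, 7.6]
    - [1.0, 7.4]
    - [2.0, 7.15]
    - [3.0, 7.0]
    - [6.0, 7.0]
    - [24.0, 7.0]
trajectory_noise_sd: 0.1
expression_mean: 1.0
expression_cv: 0.25
expression_24h_factor:
  persister: 2.0
  vbnc: 2.0
  susceptible_not_lysed: 0.2
  susceptible_lysed: 1.0
pi_fold_change:
  persister: 1.0
  vbnc: 1.0
  susceptible_not_lysed: 3.0
  susceptible_lysed: 1.0
lysis_window_h: [3.5, 10.0]
division_window_h: [4.0, 8.0]
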