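# Delta tnaA exposed to a 5 mM indole pulse for 20 min before treatment
# (pulse indole signalling mimic). The pulse does not significantly change
# the knockout's pH distributions, so this preset mirrors delta_tnaA except
# for its name.
name: delta_tnaA_indole_pulse_5mM
fate_probs: [0.035, 0.04, 0.925]
susceptible_lysed_fraction: 0.9
t0_ph_dist:
  persister:
    means: [7.5]
    sds: [0.15]
    weights: [1.0]
  vbnc:
    means: [7.5]
    sds: [0.15]
    weights: [1.0]
  susceptible:
    means: [7.5]
    sds: [0.15]
    weights: [1.0]
trajectory_anchors:
  persister:
    - [0.0, 7.5]
    - [3.0, 7.5]
    - [6.0, 7.55]
    - [24.0, 7.7]
  vbnc:
    - [0.0, 7.5]
    - [1.0, 7.4]
    - [2.0, 7.3]
    - [3.0, 7.2]
    - [6.0, 7.2]
    - [24.0, 7.2]
  susceptible:
    - [0.0, 7.5]
    - [1.0, 7.4]
    - [2.0, 7.3]
    - [3.0, 7.2]
    - [6.0, 7.2]
    - [24.0, 7.2]
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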