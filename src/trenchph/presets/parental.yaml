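# Parental (indole-positive) E. coli strain.
# Fate fractions 0.01 / 0.04 / 0.95; bimodal t=0 pH in VBNC and susceptible
# cells (peaks 7.0 and 7.6, mixture means 7.26 / 7.28); persisters a single
# tighter peak with mean 7.04. Trajectories: VBNC/susceptible acidify to a
# 3 h minimum of 7.0 and drift to 6.8 by 24 h; persisters hold their pH
# during treatment and alkalinize to 7.3 at 24 h.
name: parental
fate_probs: [0.01, 0.04, 0.95]
susceptible_lysed_fraction: 0.9
t0_ph_dist:
  persister:
    means: [7.04]
    sds: [0.15]
    weights: [1.0]
  vbnc:
    means: [7.0, 7.6]
    sds: [0.15, 0.15]
    weights: [0.5666666666666667, 0.4333333333333333]
  susceptible:
    means: [7.0, 7.6]
    sds: [0.15, 0.15]
    weights: [0.5333333333333333, 0.4666666666666667]
trajectory_anchors:
  persister:
    - [0.0, 7.04]
    - [3.0, 7.04]
    - [6.0, 7.15]
    - [24.0, 7.3]
  vbnc:
    - [0.0, 7.26]
    - [1.0, 7.15]
    - [2.0, 7.05]
    - [3.0, 7.0]
    - [6.0, 7.0]
    - [24.0, 6.8]
  susceptible:
    - [0.0, 7.28]
    - [1.0, 7.15]
    - [2.0, 7.05]
    - [3.0, 7.0]
    - [6.0, 7.0]
    - [24.0, 6.8]
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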