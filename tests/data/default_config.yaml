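schedule:
  n_blocks: 60
  block_ms: 30000
  seed: 0
profile:
  timing:
    t_straight_IJA:
      family: lnorm
      mu: 6.72
      rho: 0.46
    t_object_IJA:
      family: lnorm
      mu: 6.5
      rho: 0.58
    t_back_IJA:
      family: lnorm
      mu: 7.26
      rho: 0.44
    t_follow_RJA:
      family: exgauss
      mu: 350.0
      rho: 34.2
      eta: 124.0
    t_object_RJA:
      family: lnorm
      mu: 6.84
      rho: 0.27
    t_object_PO:
      family: lnorm
      mu: 5.92
      rho: 0.53
    t_agent_PO:
      family: norm
      mu: 2480.0
      rho: 1670.0
    t_object_OO:
      family: exgauss
      mu: 566.0
      rho: 358.0
      eta: 824.0
    t_agent_OO:
      family: lnorm
      mu: 6.27
      rho: 0.67
    t_object_INT:
      family: lnorm
      mu: 6.04
      rho: 0.59
    t_agent_INT:
      family: lnorm
      mu: 7.27
      rho: 1.04
  response_probability: 0.85
  direct_next_object_probability: 0.2
  response_window: 2000
layout:
  A:
  - 760.0
  - 340.0
  - 1160.0
  - 740.0
  O1:
  - 80.0
  - 460.0
  - 440.0
  - 820.0
  O2:
  - 380.0
  - 10.0
  - 740.0
  - 370.0
  O3:
  - 1480.0
  - 460.0
  - 1840.0
  - 820.0
  O4:
  - 1180.0
  - 10.0
  - 1540.0
  - 370.0
sampling:
  rate: 60.0
  noise_sd: 2.0
  jitter_sd: 3.0
  jitter_interval_ms: 100.0
  dropout_probability: 0.0
parsing:
  dispersion_px: 40.0
  min_fixation_ms: 60.0
  gap_bridge_ms: 75.0
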