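# Example hydrataxis configuration. Every key is optional except
# extraction.px_to_mm; omitted keys take the defaults shown here (the
# loader logs every default it applies).

geometry:
  lane_length: 50.0          # mm; light plane at x = 0
  lane_width: 5.0            # mm
  phototaxis_threshold: 10.0 # mm from the light plane
  start_zone: [23.0, 35.0]   # mm from the light plane
  frame_interval: 1.0        # seconds per frame

extraction:
  px_to_mm: 1.0              # REQUIRED: pixel-to-mm scale of the pose files
  confidence_cutoff: 0.6     # drop frames with any likelihood below this
  downsample_every: 20       # keep every N-th retained frame
  epsilon_mm: 1.0            # jump detection displacement threshold
  min_dwell: 2               # quiet samples required between separate jumps
  activity_cutoff: 3         # fed animals with <= this many jumps are inactive
  horizon_h: 8.0             # analysis window, hours
  pre_jump_only: false       # restrict theta series to pre-jump samples

model:
  w: 0.8                     # bias weight of the BCRW
  omega_t: 0.0               # target direction in the heading frame
  phi_noise:   {mu: 0.0, sigma: 30.0, nu: 5.0, lower: -180.0, upper: 180.0}
  delta_noise: {mu: 0.0, sigma: 10.0, nu: 5.0, lower: -180.0, upper: 180.0}
  lambda_starved: 2.0        # jumps per hour
  lambda_fed_active: 0.8
  lambda_fed_inactive: 0.1
  fed_active_fraction: 0.5
  jump_distances_mm: null    # null -> built-in default sample
  kde_bandwidth_mm: null     # null -> Silverman's rule
  dt_s: 20.0                 # model iteration step
  horizon_h: 8.0             # termination time

simulation:
  n_starved: 24
  n_fed: 31
  jitter_sd_mm: 0.05         # tracking jitter of the synthetic pose output
  body_length_mm: 3.0        # foot-to-head distance when rendering
  corrupt_fraction: 0.02     # share of frames with a teleported body point
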