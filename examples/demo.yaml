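# Demo: two conditions with a 25-fold gap in SR-complex formation rate,
# analyzed end to end (simulate -> QC -> events -> rates -> report).
seed: 7
kinetics:
  k_form: 1.7e-3      # s^-1, wild-type-like synapsis
  k_dissolve: 2.0e-3  # s^-1
  p_ligate: 0.5
  E_high: 0.5
  E_low: 0.05
acquisition:
  exposure: 1.0       # s
  frame_period: 2.0   # s
  cycle: [4, 1]       # donor frames : direct-acceptor frames
  fov_duration: 900.0 # s (15 min per field of view)
  n_fovs_per_replicate: 3
  n_replicates: 3
  n_molecules_per_fov: 40
events:
  threshold: 0.25
  min_frames: 5
conditions:
  wt: {k_form: 1.7e-3}
  tail_truncated: {k_form: 6.8e-5}
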