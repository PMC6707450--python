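# Reference ensemble: nominal cell (n=1000, fs=0.5, mu=0.023/day) at a
# tenth of the biological network-rate magnitude; 1000 days, 21 records.
model:
  calibrate: replication
  mu: 0.023
  n_target: 1000
  fs_target: 0.5
  beta_over_mu: 1000
  b: 1.0e-4
  M: 0.1
experiment:
  kind: simulate
  h0: 0.3
  t_max: 1000
  n_record: 21
  n_traj: 500
seed: 1
scale: desk
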