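# Selective-fusion clearance sweep over the fusion:fission ratio.
model:
  calibrate: replication
  n_target: 200
  M: 0.1
experiment:
  kind: qc_sweep
  eps_f: 4.0
  eps_m: 0.0
  ratio_grid: [0.01, 0.1, 1.0, 10.0, 100.0]
  t_eval: 1000
  h0: 0.3
  n_iter: 500
seed: 7
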