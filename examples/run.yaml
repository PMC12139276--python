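# Full pipeline on the synthetic preset at desk scale.
# Run:  enteroguild run --config examples/run.yaml
seed: 7
out_dir: runs/demo

simulate:
  n_genera: 80
  k_true: 5
  driver_weight: 0.5
  n_samples: 400
  n_snp: 2000
  h2: 0.30

rank:
  k_min: 2
  k_max: 8
  n_repetitions: 20

fit:
  k: null          # use the rank selected above
  n_restarts: 20

characterize:
  group: batch
  coverage: 0.90

assoc:
  traits: [cortisol, ADG]

h2:
  n_iter: 20000    # study-scale schedule: 100000 / burn_in 500 / thin 5
  burn_in: 500
  thin: 5
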