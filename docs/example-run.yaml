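# Reference Model 2 simulation (N = 162): fgmem run --config docs/example-run.yaml
lattice:
  subdivision: 4
model:
  variant: model2
  lambda: 0.5
  kappa: 10
  c: 8.37
  phi0: 0.8
schedule:
  thermalization: 50000
  measurement: 200000
  measure_interval: 100
  tuning_interval: 500
  seed: 3
output:
  dir: fgmem-out
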