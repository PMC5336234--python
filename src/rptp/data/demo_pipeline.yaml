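# Demo pipeline configuration: simulate the default R3-like family and run
# every stage.  `rptp run --config <this file> --out results/demo`
seed: 42

simulate: {}          # default study conditions (see rptp.simulate)

similarity:
  threshold: 1.0e-80

msa:
  costs: [1, 2, 4, 6, 8, 16]

phylo:
  n_starts: 10
  bootstrap: 100
  boot_starts: 1

synteny:
  packaged: true      # the PTPRB-vs-Ciona worked example shipped with rptp
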