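{
  "landscape": {"kind": "uniform", "n_bins": 3, "p": 0.5},
  "nfork": 2,
  "pprogress": 1.0,
  "prelease": 0.0,
  "initiation_mode": "per_pair",
  "n_cycles": 10000,
  "se_mult": 3,
  "engine": {"ncells": 200, "ntherm": 10, "nmeas": 4, "stepsize": 150}
}
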