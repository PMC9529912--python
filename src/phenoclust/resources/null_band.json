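[
  {
    "n": 36,
    "n_pcs": 2,
    "oracle_trials": 20000,
    "mean": 56.4619,
    "sd": 4.9794,
    "q025": 50.0,
    "q975": 69.4444
  },
  {
    "n": 36,
    "n_pcs": 1,
    "oracle_trials": 20000,
    "mean": 56.4761,
    "sd": 4.9586,
    "q025": 50.0,
    "q975": 66.6667
  }
]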