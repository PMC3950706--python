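{
  "background_rate": 0.02,
  "control_hotspots": 3,
  "dataset_folds": {
    "endogenous": {
      "discordant": 8.0,
      "shared": 1.0
    },
    "tagged_mut": {
      "discordant": 1.0,
      "shared": 0.9
    },
    "tagged_wt": {
      "discordant": 1.0,
      "shared": 1.2
    }
  },
  "duplicate_burst": [
    0.001,
    12
  ],
  "frac_discordant": 0.25,
  "frac_tss_peaks": 0.8,
  "genome": [
    [
      "chr1",
      200000
    ]
  ],
  "n_genes": 24,
  "n_peaks": 16,
  "ortholog_frac": 0.7,
  "peak_depth": 100.0,
  "seed": 7
}
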