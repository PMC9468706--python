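{
  "alpha_j": [
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0,
    0.0
  ],
  "bx_true": [
    0.7157981544506968,
    0.41469030948634006,
    0.588567398785878,
    0.8178559721808828,
    0.23194061974144375,
    0.6637040736479289,
    0.4243952671201816,
    0.695466619638579,
    0.21202569318365125,
    0.5303062120639703,
    0.18025277646645488,
    0.5717209092776867,
    0.6689919699955181,
    0.6342124531064613,
    0.3668194427616384,
    0.6608027867450342,
    0.2932685843187398,
    0.849249326313827,
    0.19629438839394187,
    0.17782503055564963,
    0.5132775633742291,
    0.27563770809240973,
    0.20369191057799485,
    0.21326258269965923,
    0.8986516026864347,
    0.2596763348995629,
    0.810762734958698,
    0.3330559371281603,
    0.8908035828818612,
    0.8089178976478322,
    0.5347585709892825
  ],
  "config": {
    "exposure_or_range": [
      1.18,
      2.53
    ],
    "inside_violation": 0.0,
    "maf_range": [
      0.1,
      0.4
    ],
    "n_exp": 14267,
    "n_ld_blocks": 31,
    "n_out": 180866,
    "n_snps": 31,
    "pleio_frac": 0.0,
    "pleio_mean": 0.0,
    "pleio_sd": 0.0,
    "seed": 988022,
    "true_beta": -0.005
  },
  "outlier_ids": [],
  "seed": 988022,
  "true_beta": -0.005
}
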