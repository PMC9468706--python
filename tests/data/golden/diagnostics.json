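{
  "egger_intercept": {
    "beta": -0.0007516245649843684,
    "ci_high": 0.002750391883641491,
    "ci_low": -0.004253641013610228,
    "method": "egger_intercept",
    "n_snp": 31,
    "or": 0.9992486578340019,
    "or_ci_high": 1.0027541776814117,
    "or_ci_low": 0.9957553929037731,
    "pval": 0.6639438476034724,
    "se": 0.0017122852008804566,
    "seed": null
  },
  "presso": {
    "beta_corrected": {
      "beta": -0.00510317182135546,
      "ci_high": -0.0025521896337487053,
      "ci_low": -0.007654154008962215,
      "method": "ivw_re",
      "n_snp": 31,
      "or": 0.9949098272384181,
      "or_ci_high": 0.9974510644332939,
      "or_ci_low": 0.9923750644328242,
      "pval": 8.823510045353819e-05,
      "se": 0.0013015454404920587,
      "seed": null
    },
    "beta_raw": {
      "beta": -0.00510317182135546,
      "ci_high": -0.0025521896337487053,
      "ci_low": -0.007654154008962215,
      "method": "ivw_re",
      "n_snp": 31,
      "or": 0.9949098272384181,
      "or_ci_high": 0.9974510644332939,
      "or_ci_low": 0.9923750644328242,
      "pval": 8.823510045353819e-05,
      "se": 0.0013015454404920587,
      "seed": null
    },
    "distortion_p": null,
    "global_p": 0.8051948051948052,
    "global_rss_obs": 24.542423102107087,
    "n_sim": 1000,
    "outlier_pvals": {
      "rs000001": 1.0,
      "rs000002": 1.0,
      "rs000003": 1.0,
      "rs000004": 1.0,
      "rs000005": 1.0,
      "rs000006": 1.0,
      "rs000007": 1.0,
      "rs000008": 1.0,
      "rs000009": 1.0,
      "rs000010": 1.0,
      "rs000011": 1.0,
      "rs000012": 1.0,
      "rs000013": 1.0,
      "rs000014": 1.0,
      "rs000015": 1.0,
      "rs000016": 1.0,
      "rs000017": 1.0,
      "rs000018": 1.0,
      "rs000019": 1.0,
      "rs000020": 1.0,
      "rs000021": 1.0,
      "rs000022": 1.0,
      "rs000023": 1.0,
      "rs000024": 1.0,
      "rs000025": 1.0,
      "rs000026": 1.0,
      "rs000027": 1.0,
      "rs000028": 1.0,
      "rs000029": 1.0,
      "rs000030": 1.0,
      "rs000031": 1.0
    },
    "outliers": [],
    "seed": 20220830
  },
  "q_egger": {
    "df": 29,
    "p": 0.787827751008487,
    "q": 22.750676253858366
  },
  "q_ivw": {
    "df": 30,
    "p": 0.8175810641959078,
    "q": 22.943362060194353
  }
}
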