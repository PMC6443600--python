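{
  "feature_ids": [
    "glcm_cluster_shade_a",
    "firstorder_variance_a",
    "glrlm_lgre_a",
    "gabor_variance_a",
    "gabor_variance_b",
    "gabor_variance_c",
    "gabor_entropy_a",
    "gabor_variance_d"
  ],
  "weights": [
    5.65412e-11,
    -2.726245e-04,
    -19.80131,
    -3.909510e-03,
    -1.039332e-17,
    -1.021795e-05,
    6.648282e-02,
    -5.733282e-11
  ],
  "cutoff": -1.117,
  "reference_flag": true,
  "alpha": null
}
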