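{
  "startprob": [
    0.6666666666666667,
    0.16666666666666669,
    0.16666666666666669
  ],
  "transmat": [
    [
      0.997057925623743,
      0.0014710371881285404,
      0.0014710371881285404
    ],
    [
      0.03560035836903468,
      0.9643640768373899,
      3.556479357545923e-05
    ],
    [
      0.02062332254035114,
      2.0602719820530608e-05,
      0.9793560747398283
    ]
  ],
  "emissionprob": [
    [
      0.9270786163296543,
      0.07146478071921121,
      0.001456602951134574
    ],
    [
      0.03206494107229402,
      0.8781164507267449,
      0.08981860820096116
    ],
    [
      0.01937549594838853,
      0.6268335000943261,
      0.3537910039572853
    ]
  ],
  "metadata": {
    "bin_size": 5000,
    "threshold": 0.075,
    "species": [
      "train_01",
      "train_02",
      "train_03",
      "train_04",
      "train_05",
      "train_06"
    ],
    "n_models_averaged": 6,
    "training_corpus": "synthetic (simulate_corpus seed=7, 6 training species)"
  },
  "state_names": [
    "none",
    "flam_like",
    "centromere_like"
  ]
}
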