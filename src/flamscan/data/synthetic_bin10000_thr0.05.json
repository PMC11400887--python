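{
  "startprob": [
    0.6666666666666667,
    0.16666666666666669,
    0.16666666666666669
  ],
  "transmat": [
    [
      0.9941058274733022,
      0.002947086263348902,
      0.002947086263348902
    ],
    [
      0.0717880488923189,
      0.9281402347751212,
      7.171633255975915e-05
    ],
    [
      0.04055611792650102,
      4.051560232417685e-05,
      0.9594033664711749
    ]
  ],
  "emissionprob": [
    [
      0.8749412372055677,
      0.12109437135928872,
      0.003964391435143646
    ],
    [
      0.058787491604829066,
      0.7695546054679182,
      0.17165790292725278
    ],
    [
      0.036058105206655935,
      0.27641807568438004,
      0.6875238191089641
    ]
  ],
  "metadata": {
    "bin_size": 10000,
    "threshold": 0.05,
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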