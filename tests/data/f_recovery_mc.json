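{
  "conditions": {
    "n_animals": 5,
    "residual_cv_pct": 15.0,
    "f_true": 0.25,
    "n_replicates": 400
  },
  "intervals": {
    "40": {
      "lo": 21.917734319513123,
      "hi": 26.765934312969417,
      "mean": 24.191109249389473
    },
    "20": {
      "lo": 21.757919066325464,
      "hi": 26.205527018380632,
      "mean": 24.13756110449349
    }
  }
}
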