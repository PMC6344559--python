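{
  "n_episodes": 40,
  "n_events": 7,
  "n_high_risk": 9,
  "characteristics": {
    "confusion": {
      "tp": 4,
      "fp": 5,
      "fn": 3,
      "tn": 28
    },
    "sensitivity": {
      "estimate": 0.5714285714285714,
      "lower": 0.20237169360648533,
      "upper": 0.8819169887384475
    },
    "specificity": {
      "estimate": 0.8484848484848485,
      "lower": 0.6733170573796703,
      "upper": 0.9428412273181301
    },
    "ppv": {
      "estimate": 0.4444444444444444,
      "lower": 0.15343055750857953,
      "upper": 0.7734707701106026
    },
    "npv": {
      "estimate": 0.9032258064516129,
      "lower": 0.7309964153624848,
      "upper": 0.9746681146476046
    },
    "lr_positive": {
      "estimate": 3.771428571428572,
      "lower": 1.3447493345137016,
      "upper": 10.577193164800063
    },
    "lr_negative": {
      "estimate": 0.5051020408163266,
      "lower": 0.21215064352845778,
      "upper": 1.2025797678176513
    }
  },
  "auroc": {
    "auc": 0.7099567099567099,
    "ci_lower": 0.4785694991891183,
    "ci_upper": 0.9413439207243015
  }
}
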