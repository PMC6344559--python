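{
  "outcome_name": "deterioration",
  "baseline_rate": 0.15,
  "root": "1",
  "nodes": [
    {
      "id": "1",
      "n": 400,
      "n_event": 44,
      "event_rate": 0.11,
      "variable": "il8",
      "threshold": 1070.0,
      "children": [
        "2",
        "3"
      ]
    },
    {
      "id": "2",
      "n": 340,
      "n_event": 13,
      "event_rate": 0.03823529411764706,
      "risk_label": "low"
    },
    {
      "id": "3",
      "n": 60,
      "n_event": 31,
      "event_rate": 0.5166666666666667,
      "risk_label": "high"
    }
  ]
}
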