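{
  "outcome_name": "mortality28",
  "baseline_rate": 0.0525,
  "root": "1",
  "nodes": [
    {
      "id": "1",
      "n": 400,
      "n_event": 27,
      "event_rate": 0.0675,
      "variable": "il8",
      "threshold": 974.0,
      "children": [
        "2",
        "3"
      ]
    },
    {
      "id": "2",
      "n": 330,
      "n_event": 10,
      "event_rate": 0.030303030303030304,
      "risk_label": "low"
    },
    {
      "id": "3",
      "n": 70,
      "n_event": 17,
      "event_rate": 0.24285714285714285,
      "risk_label": "high"
    }
  ]
}
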