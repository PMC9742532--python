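{
  "name": "adart_placeholder",
  "comment": "SYNTHETIC PLACEHOLDER point values in the ADA risk-test schema (positivity at total score >= 5). The published ADART point table is not redistributed here; edit this file to supply real points.",
  "cutoff": 5,
  "items": [
    {
      "feature": "age",
      "bins": [
        {"lo": null, "hi": 40, "points": 0},
        {"lo": 40, "hi": 50, "points": 1},
        {"lo": 50, "hi": 60, "points": 2},
        {"lo": 60, "hi": null, "points": 3}
      ]
    },
    {
      "feature": "sex",
      "bins": [
        {"categories": ["female"], "points": 0},
        {"categories": ["male"], "points": 1}
      ]
    },
    {
      "feature": "sbp",
      "bins": [
        {"lo": null, "hi": 140, "points": 0},
        {"lo": 140, "hi": null, "points": 1}
      ]
    },
    {
      "feature": "physical_activity",
      "bins": [
        {"categories": ["active"], "points": 0},
        {"categories": ["inactive"], "points": 1}
      ]
    },
    {
      "feature": "bmi",
      "bins": [
        {"lo": null, "hi": 25, "points": 0},
        {"lo": 25, "hi": 30, "points": 1},
        {"lo": 30, "hi": 40, "points": 2},
        {"lo": 40, "hi": null, "points": 3}
      ]
    }
  ]
}
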