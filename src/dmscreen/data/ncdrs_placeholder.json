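{
  "name": "ncdrs_placeholder",
  "comment": "SYNTHETIC PLACEHOLDER point values in the NCDRS schema (age/sex/BMI/WC/SBP items, positivity at total score >= 25). The published New Chinese Diabetes Risk Score point table is not redistributed here; edit this file to supply real points.",
  "cutoff": 25,
  "items": [
    {
      "feature": "age",
      "bins": [
        {"lo": null, "hi": 25, "points": 0},
        {"lo": 25, "hi": 35, "points": 2},
        {"lo": 35, "hi": 40, "points": 4},
        {"lo": 40, "hi": 45, "points": 6},
        {"lo": 45, "hi": 50, "points": 8},
        {"lo": 50, "hi": 55, "points": 10},
        {"lo": 55, "hi": 60, "points": 11},
        {"lo": 60, "hi": 65, "points": 12},
        {"lo": 65, "hi": null, "points": 13}
      ]
    },
    {
      "feature": "sex",
      "bins": [
        {"categories": ["female"], "points": 0},
        {"categories": ["male"], "points": 2}
      ]
    },
    {
      "feature": "bmi",
      "bins": [
        {"lo": null, "hi": 22, "points": 0},
        {"lo": 22, "hi": 24, "points": 1},
        {"lo": 24, "hi": 30, "points": 3},
        {"lo": 30, "hi": null, "points": 5}
      ]
    },
    {
      "feature": "wc",
      "bins": [
        {"lo": null, "hi": 75, "points": 0},
        {"lo": 75, "hi": 80, "points": 3},
        {"lo": 80, "hi": 85, "points": 5},
        {"lo": 85, "hi": 90, "points": 7},
        {"lo": 90, "hi": 95, "points": 8},
        {"lo": 95, "hi": null, "points": 10}
      ]
    },
    {
      "feature": "sbp",
      "bins": [
        {"lo": null, "hi": 110, "points": 0},
        {"lo": 110, "hi": 120, "points": 1},
        {"lo": 120, "hi": 130, "points": 3},
        {"lo": 130, "hi": 140, "points": 6},
        {"lo": 140, "hi": 150, "points": 7},
        {"lo": 150, "hi": 160, "points": 8},
        {"lo": 160, "hi": null, "points": 10}
      ]
    }
  ]
}
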