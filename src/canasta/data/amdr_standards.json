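[
  {
    "name": "INCAP",
    "bounds": {
      "protein": [10, 15],
      "fat": [20, 25],
      "carb": [60, 70]
    }
  },
  {
    "name": "INDECI",
    "bounds": {
      "protein": [10, 15],
      "fat": [20, 35],
      "carb": [50, 65]
    }
  }
]
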