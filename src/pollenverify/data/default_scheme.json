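{
  "name": "austrian-4-class",
  "interval_fraction": 0.2,
  "plain_classes": [
    {"label": "no", "lower": 0, "upper": 1},
    {"label": "low", "lower": 1, "upper": 20},
    {"label": "moderate", "lower": 20, "upper": 50},
    {"label": "high", "lower": 50, "upper": null}
  ],
  "intermediate_classes": [
    {"label": "no-low", "pair": ["no", "low"], "band": [0, 2]},
    {"label": "low-moderate", "pair": ["low", "moderate"]},
    {"label": "moderate-high", "pair": ["moderate", "high"]}
  ]
}
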