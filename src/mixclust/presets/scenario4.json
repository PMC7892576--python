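{
  "scenario": 4,
  "description": "degree of relevance of continuous variables low / mild / high",
  "levels": [
    {
      "label": "cont-degree=low",
      "degree_continuous": "low"
    },
    {
      "label": "cont-degree=mild",
      "degree_continuous": "mild"
    },
    {
      "label": "cont-degree=high",
      "degree_continuous": "high"
    }
  ]
}
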