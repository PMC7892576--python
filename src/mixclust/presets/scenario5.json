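{
  "scenario": 5,
  "description": "degree of relevance of categorical variables low / mild / high",
  "levels": [
    {
      "label": "cat-degree=low",
      "degree_categorical": "low"
    },
    {
      "label": "cat-degree=mild",
      "degree_categorical": "mild"
    },
    {
      "label": "cat-degree=high",
      "degree_categorical": "high"
    }
  ]
}
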