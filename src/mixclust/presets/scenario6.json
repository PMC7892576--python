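{
  "scenario": 6,
  "description": "proportion of relevant categorical variables 20/50/90% of 10",
  "levels": [
    {
      "label": "cat-relevant=20%",
      "n_categorical": 10,
      "prop_relevant_categorical": 0.2
    },
    {
      "label": "cat-relevant=50%",
      "n_categorical": 10,
      "prop_relevant_categorical": 0.5
    },
    {
      "label": "cat-relevant=90%",
      "n_categorical": 10,
      "prop_relevant_categorical": 0.9
    }
  ]
}
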