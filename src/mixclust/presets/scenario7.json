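{
  "scenario": 7,
  "description": "proportion of relevant continuous variables 20/50/90% of 10",
  "levels": [
    {
      "label": "cont-relevant=20%",
      "n_continuous": 10,
      "prop_relevant_continuous": 0.2
    },
    {
      "label": "cont-relevant=50%",
      "n_continuous": 10,
      "prop_relevant_continuous": 0.5
    },
    {
      "label": "cont-relevant=90%",
      "n_continuous": 10,
      "prop_relevant_continuous": 0.9
    }
  ]
}
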