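{
  "scenario": 3,
  "description": "variable counts 2 / 4 / 8 for one type, the other fixed at 4",
  "levels": [
    {
      "label": "cont=2",
      "n_continuous": 2
    },
    {
      "label": "cont=4",
      "n_continuous": 4
    },
    {
      "label": "cont=8",
      "n_continuous": 8
    },
    {
      "label": "cat=2",
      "n_categorical": 2
    },
    {
      "label": "cat=4",
      "n_categorical": 4
    },
    {
      "label": "cat=8",
      "n_categorical": 8
    }
  ]
}
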