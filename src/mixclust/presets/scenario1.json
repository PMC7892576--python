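{
  "scenario": 1,
  "description": "population size 300 / 600 / 1200, all else at baseline",
  "levels": [
    {
      "label": "N=300",
      "population_size": 300
    },
    {
      "label": "N=600",
      "population_size": 600
    },
    {
      "label": "N=1200",
      "population_size": 1200
    }
  ]
}
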