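{
  "scenario": 2,
  "description": "number of clusters 2 / 6 / 10",
  "levels": [
    {
      "label": "G=2",
      "n_clusters": 2
    },
    {
      "label": "G=6",
      "n_clusters": 6
    },
    {
      "label": "G=10",
      "n_clusters": 10
    }
  ]
}
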