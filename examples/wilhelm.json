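{
  "species": [
    "X",
    "Y"
  ],
  "fixed": {
    "S": 1.0
  },
  "parameters": {
    "k1": 8.0,
    "k2": 1.0,
    "k3": 1.0,
    "k4": 1.5
  },
  "reactions": [
    {
      "reactants": {
        "S": 1,
        "Y": 1
      },
      "products": {
        "X": 2
      },
      "k": "k1"
    },
    {
      "reactants": {
        "X": 2
      },
      "products": {
        "X": 1,
        "Y": 1
      },
      "k": "k2"
    },
    {
      "reactants": {
        "X": 1,
        "Y": 1
      },
      "products": {
        "Y": 1
      },
      "k": "k3"
    },
    {
      "reactants": {
        "X": 1
      },
      "products": {},
      "k": "k4"
    }
  ]
}
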