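{
  "id": "T1",
  "metabolites": [
    {
      "id": "glc_e",
      "name": "glucose",
      "compartment": "external",
      "carbon": 6
    },
    {
      "id": "co2_e",
      "name": "carbon dioxide",
      "compartment": "external",
      "carbon": 1
    }
  ],
  "reactions": [
    {
      "id": "EX_glc",
      "stoich": {
        "glc_e": -1
      },
      "lb": -10,
      "ub": 0,
      "exchange": true
    },
    {
      "id": "GROWTH",
      "stoich": {
        "glc_e": -10,
        "co2_e": 12
      },
      "lb": 0,
      "ub": null,
      "exchange": false
    },
    {
      "id": "EX_co2",
      "stoich": {
        "co2_e": -1
      },
      "lb": 0,
      "ub": null,
      "exchange": true
    }
  ],
  "couplings": [],
  "objective": "GROWTH",
  "biomass_carbon": 48.0
}
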