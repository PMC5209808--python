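{
  "model_kind": "gap",
  "version": "1.0",
  "criteria": [
    {
      "name": "Diagnostic tools",
      "scale": {
        "values": [
          -2,
          -1,
          0,
          1,
          2
        ]
      },
      "sub_criteria": [
        "Availability",
        "Prevention and control - Differentiation of infected from vaccinated (DIVA)",
        "Strategic reserve",
        "Capacity of production",
        "Market potential",
        "Affordable",
        "Quality/stability durability",
        "Sensitivity",
        "Specificity",
        "Reproducibility",
        "Simplicity/ease of use",
        "Speed"
      ],
      "availability_marker": 1
    },
    {
      "name": "Vaccination tools",
      "scale": {
        "values": [
          -2,
          -1,
          0,
          1,
          2
        ]
      },
      "sub_criteria": [
        "Commercial availability",
        "Monitoring for infection in a vaccinated population",
        "Strategic reserve",
        "Capacity of production",
        "Market potential",
        "Affordable",
        "Quality/stability",
        "Safety of vaccines",
        "Efficacy",
        "Immunity",
        "Convenience of use"
      ],
      "availability_marker": 1
    },
    {
      "name": "Pharmaceutical tools",
      "scale": {
        "values": [
          -2,
          -1,
          0,
          1,
          2
        ]
      },
      "sub_criteria": [
        "Availability",
        "Prevention and control",
        "Strategic reserve",
        "Capacity of production",
        "Market potential",
        "Cost",
        "Quality",
        "Safety animal",
        "Safety consumer/user concerns",
        "Safety environment",
        "Resistance"
      ],
      "availability_marker": 1
    }
  ]
}
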