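{
  "model_kind": "prioritisation",
  "version": "1.0",
  "criteria": [
    {
      "name": "Disease knowledge",
      "scale": {
        "values": [
          0,
          1,
          2,
          3,
          4
        ]
      },
      "sub_criteria": [
        "Speed of spread",
        "Number of species involved",
        "Persistence of infectious agent in the environment",
        "Risk of spread to susceptible populations",
        "Potential for silent spread",
        "Wildlife reservoir and potential spread",
        "Vector reservoir and potential spread",
        "Variability of the agent",
        "Understanding of fundamental immunology",
        "Host pathogen interaction"
      ]
    },
    {
      "name": "Impact on animal health and welfare",
      "scale": {
        "values": [
          0,
          1,
          2,
          3,
          4
        ]
      },
      "sub_criteria": [
        "Disease impact on production",
        "Duration of animal welfare impact",
        "Proportion of animals affected and suffering pain/injury/distress as a result of the disease"
      ]
    },
    {
      "name": "Impact on public health \u2013 human health",
      "scale": {
        "values": [
          0,
          1,
          2,
          3,
          4
        ]
      },
      "sub_criteria": [
        "Impact of occurrence on human health",
        "Likelihood of occurrence",
        "Impact of occurrence on food safety",
        "Transmissibility (spread from animals to humans)",
        "Spread in humans",
        "Bioterrorism potential"
      ]
    },
    {
      "name": "Impact on wider society",
      "scale": {
        "values": [
          0,
          1,
          2,
          3,
          4
        ]
      },
      "sub_criteria": [
        "Economic direct impact (including cumulative cost, e.g. enzootic vs. epizootic)",
        "Economic indirect impact (social, market)",
        "Agriterrorism potential"
      ]
    },
    {
      "name": "Impact on trade",
      "scale": {
        "values": [
          0,
          1,
          2,
          3,
          4
        ]
      },
      "sub_criteria": [
        "Impact on international trade due to existing regulations",
        "Impact on EC trade due to existing regulations",
        "Potential for regionalisation",
        "Impact on security of food supply"
      ]
    },
    {
      "name": "Control tools",
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
        "Appropriate diagnostics",
        "Appropriate vaccines",
        "Appropriate pharmaceuticals"
      ]
    }
  ]
}
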