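[
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 2000, "max": 3000},
      {"attribute": "gestational_age", "min": 38, "max": 42},
      {"attribute": "gender"},
      {"attribute": "concentration"}
    ],
    "n_records": 6000
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 400, "max": 1000},
      {"attribute": "gestational_age", "min": 24, "max": 28},
      {"attribute": "gender"}
    ],
    "n_records": 1500
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 1000, "max": 1500},
      {"attribute": "gestational_age", "min": 26, "max": 30},
      {"attribute": "gender"}
    ],
    "n_records": 2000
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 1500, "max": 2500},
      {"attribute": "gestational_age", "min": 30, "max": 36},
      {"attribute": "gender", "categorical_values": ["M"]}
    ],
    "n_records": 2500
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 1500, "max": 2500},
      {"attribute": "gestational_age", "min": 30, "max": 36},
      {"attribute": "gender", "categorical_values": ["F"]}
    ],
    "n_records": 2500
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 2500, "max": 4000},
      {"attribute": "gestational_age", "min": 36, "max": 42},
      {"attribute": "gender"}
    ],
    "n_records": 4000
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 3000, "max": 4500},
      {"attribute": "gestational_age", "min": 37, "max": 42},
      {"attribute": "gender", "categorical_values": ["M"]}
    ],
    "n_records": 1500
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 3000, "max": 4500},
      {"attribute": "gestational_age", "min": 37, "max": 42},
      {"attribute": "gender", "categorical_values": ["F"]}
    ],
    "n_records": 1500
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 400, "max": 1500},
      {"attribute": "gender"}
    ],
    "n_records": 1000
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "gestational_age", "min": 24, "max": 32},
      {"attribute": "gender"}
    ],
    "n_records": 3000
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "gestational_age", "min": 32, "max": 37},
      {"attribute": "gender"}
    ],
    "n_records": 3000
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "gestational_age", "min": 37, "max": 42},
      {"attribute": "gender"}
    ],
    "n_records": 3000
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 2000, "max": 3500},
      {"attribute": "gestational_age", "min": 34, "max": 40},
      {"attribute": "gender", "categorical_values": ["M"]}
    ],
    "n_records": 2000
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 2000, "max": 3500},
      {"attribute": "gestational_age", "min": 34, "max": 40},
      {"attribute": "gender", "categorical_values": ["F"]}
    ],
    "n_records": 2000
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 1000, "max": 2000},
      {"attribute": "gestational_age", "min": 28, "max": 34},
      {"attribute": "gender"},
      {"attribute": "concentration"}
    ],
    "n_records": 2500
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 2500, "max": 3500},
      {"attribute": "gender", "categorical_values": ["M"]}
    ],
    "n_records": 1800
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 2500, "max": 3500},
      {"attribute": "gender", "categorical_values": ["F"]}
    ],
    "n_records": 1800
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 400, "max": 5000},
      {"attribute": "gestational_age", "min": 24, "max": 42},
      {"attribute": "gender"}
    ],
    "n_records": 6000
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 1800, "max": 2800},
      {"attribute": "gestational_age", "min": 33, "max": 38},
      {"attribute": "gender"}
    ],
    "n_records": 1200
  },
  {
    "keywords": ["Gentamicin", "neonates"],
    "constraints": [
      {"attribute": "body_weight", "min": 3500, "max": 5000},
      {"attribute": "gestational_age", "min": 38, "max": 42},
      {"attribute": "gender"}
    ],
    "n_records": 800
  }
]
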