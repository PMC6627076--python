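{
  "genome_length_bp": 16569,
  "proliferating": true,
  "halving_factor": 2.0,
  "age_years": 70.0,
  "copy_number": {
    "kind": "log10_uniform",
    "lower": 2.0,
    "upper": 4.0
  },
  "polg_error_rate": {
    "kind": "uniform",
    "lower": 2.8e-08,
    "upper": 5.6e-07
  },
  "x1": {
    "kind": "uniform",
    "lower": 10.0,
    "upper": 80.0
  },
  "x2": {
    "kind": "uniform",
    "lower": 180.0,
    "upper": 380.0
  },
  "x3": {
    "kind": "uniform",
    "lower": 81.0,
    "upper": 101.0
  },
  "half_life_days": 91.3125,
  "hsc_cycle_weeks": 40.0,
  "days_per_year": 365.25,
  "weeks_per_year": 52.18
}
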