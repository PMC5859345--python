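{
  "version": "iwpc-2009",
  "comment": "IWPC dosing equations on the square-root-of-weekly-dose (mg/week) scale. Age enters in decades (age/10), height in cm, weight in kg; genotype, race and drug terms are 0/1 indicators. Override any key via a user coefficient file.",
  "pgx": {
    "intercept": 5.6044,
    "age_decades": -0.2614,
    "height_cm": 0.0087,
    "weight_kg": 0.0128,
    "vkorc1_GA": -0.8677,
    "vkorc1_AA": -1.6974,
    "vkorc1_unknown": -0.4854,
    "cyp2c9_12": -0.5211,
    "cyp2c9_13": -0.9357,
    "cyp2c9_22": -1.0616,
    "cyp2c9_23": -1.9206,
    "cyp2c9_33": -2.3312,
    "cyp2c9_unknown": -0.2188,
    "race_asian": -0.1092,
    "race_black_or_african_american": -0.2760,
    "race_missing_or_mixed": -0.1032,
    "enzyme_inducer": 1.1816,
    "amiodarone": -0.5503
  },
  "clinical": {
    "intercept": 4.0376,
    "age_decades": -0.2546,
    "height_cm": 0.0118,
    "weight_kg": 0.0134,
    "race_asian": -0.6752,
    "race_black_or_african_american": 0.4060,
    "race_missing_or_mixed": 0.0443,
    "enzyme_inducer": 1.2799,
    "amiodarone": -0.5695
  }
}
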