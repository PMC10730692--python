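{
  "name": "two_hit",
  "description": "Logistic risk calculator for two-hit (biallelic) inactivation of a breast-cancer DNA-repair gene in the tumor.",
  "intercept": -2.371,
  "coefficients": {
    "age": -0.038,
    "grade": -0.055,
    "T": 0.087,
    "N": -0.032,
    "M": -0.228,
    "ER": 0.166,
    "PR": -0.185,
    "HER2": -1.879,
    "Ki67": 0.021,
    "contralateral": 0.938,
    "FHBC": 1.045,
    "FHOC": 1.075,
    "other_cancer_history": 0.506
  },
  "coding": {
    "age": "age at diagnosis, years",
    "grade": "histological grade, ordinal 1-3",
    "T": "tumor size category, ordinal 0-4",
    "N": "lymph-node category, ordinal 0-3",
    "M": "distant metastasis, 0/1",
    "ER": "estrogen receptor positive, 0/1",
    "PR": "progesterone receptor positive, 0/1",
    "HER2": "HER2 positive, 0/1",
    "Ki67": "Ki67 index, percent 0-100",
    "contralateral": "history of contralateral (bilateral) breast cancer, 0/1",
    "FHBC": "family history of breast cancer, 0/1",
    "FHOC": "family history of ovarian cancer, 0/1",
    "other_cancer_history": "family history of other cancers, 0/1"
  }
}
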