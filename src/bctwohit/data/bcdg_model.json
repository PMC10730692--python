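{
  "name": "bcdg",
  "description": "Logistic risk calculator for carrying a pathogenic germline variant in a breast-cancer DNA-repair gene (BRCA1/BRCA2/CHEK2/PALB2/TP53).",
  "intercept": -1.561,
  "coefficients": {
    "age": -0.039,
    "grade": 0.094,
    "T": -0.079,
    "N": 0.133,
    "M": -0.030,
    "ER": 0.277,
    "PR": -0.290,
    "HER2": -1.599,
    "Ki67": 0.017,
    "contralateral": 0.949,
    "FHBC": 1.074,
    "FHOC": 1.515,
    "other_cancer_history": 0.320
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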