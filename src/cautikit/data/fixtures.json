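[
  {
    "schema_version": "1",
    "case_id": "case-1",
    "isolates": [
      {
        "name": "Klebsiella pneumoniae",
        "organism_class": "gram_negative",
        "cfu": {"lower": 100000, "upper": null}
      }
    ],
    "catheter": {"in_place": true, "removed_within_48h": false, "chronic": false},
    "cues": {
      "systemic_leukocytosis": true,
      "pyuria": true,
      "elderly_or_frail": true,
      "alternative_source": {"systemic_leukocytosis": true}
    }
  },
  {
    "schema_version": "1",
    "case_id": "case-2",
    "isolates": [
      {
        "name": "gram-positive organisms",
        "organism_class": "gram_positive",
        "cfu": {"lower": 1000, "upper": 10000}
      }
    ],
    "catheter": {"in_place": true, "removed_within_48h": false, "chronic": false},
    "cues": {
      "fever_temp_f": 103.3,
      "new_onset_delirium": true,
      "acute_hematuria": true,
      "pyuria": true,
      "systemic_leukocytosis": true,
      "elderly_or_frail": true
    }
  },
  {
    "schema_version": "1",
    "case_id": "case-3",
    "isolates": [
      {
        "name": "Escherichia coli",
        "organism_class": "gram_negative",
        "cfu": {"lower": 100000, "upper": null}
      },
      {
        "name": "Klebsiella oxytoca",
        "organism_class": "gram_negative",
        "cfu": {"lower": 1000, "upper": 100000}
      }
    ],
    "catheter": {"in_place": true, "removed_within_48h": false, "chronic": false},
    "cues": {
      "weakness": true,
      "systemic_leukocytosis": true,
      "prior_uti_history": true,
      "pyuria": true,
      "elderly_or_frail": true
    }
  },
  {
    "schema_version": "1",
    "case_id": "case-4",
    "isolates": [
      {
        "name": "Candida albicans",
        "organism_class": "fungal",
        "cfu": {"lower": 100000, "upper": null}
      }
    ],
    "catheter": {"in_place": true, "removed_within_48h": false, "chronic": true},
    "cues": {
      "elderly_or_frail": true
    }
  }
]
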