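{
  "comment": "Illustrative default cue prevalences for the rater simulator. Concordant cues carry class-conditional probabilities [P(present | CA-UTI), P(present | CA-ABU)]; discordant cues carry a single probability applied identically to both classes, so they are non-informative by construction. These values are plausible desk-scale defaults, not estimates from any dataset.",
  "concordant": {
    "fever": [0.7, 0.05],
    "new_onset_delirium": [0.3, 0.05],
    "rigors": [0.2, 0.02],
    "flank_pain": [0.15, 0.02],
    "acute_hematuria": [0.1, 0.02],
    "pelvic_discomfort": [0.1, 0.02],
    "urgency": [0.25, 0.05],
    "frequency": [0.25, 0.05],
    "dysuria": [0.3, 0.05],
    "suprapubic_pain": [0.15, 0.03]
  },
  "discordant": {
    "pyuria": 0.7,
    "foul_smelling_urine": 0.3,
    "urine_color_change": 0.3,
    "urine_sediment": 0.25,
    "systemic_leukocytosis": 0.5,
    "prior_uti_history": 0.3,
    "resistant_organism": 0.2,
    "vague_malaise": 0.4,
    "weakness": 0.35,
    "elderly_or_frail": 0.6
  },
  "fever_temp_mean_c": 39.2,
  "fever_temp_sd_c": 0.6
}
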