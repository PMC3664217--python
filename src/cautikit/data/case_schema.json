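{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/cautikit/case.schema.json",
  "title": "Catheter-associated bacteriuria case record",
  "description": "One patient episode of catheter-associated bacteriuria: urine-culture isolates with interval CFU/mL counts, catheter status, structured sign/symptom flags, and per-cue alternative-source attributions. Missing cue flags mean absent (chart-review convention). Temperatures are Celsius internally; fever_temp_f is accepted on input and converted.",
  "type": "object",
  "required": ["case_id"],
  "additionalProperties": false,
  "properties": {
    "schema_version": {"type": "string", "enum": ["1"]},
    "case_id": {"type": "string", "minLength": 1},
    "isolates": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "organism_class", "cfu"],
        "additionalProperties": false,
        "properties": {
          "name": {"type": "string"},
          "organism_class": {
            "type": "string",
            "enum": ["gram_negative", "gram_positive", "fungal"]
          },
          "cfu": {
            "type": "object",
            "additionalProperties": false,
            "properties": {
              "lower": {"type": "number", "minimum": 0},
              "upper": {"type": ["number", "null"], "minimum": 0},
              "exact": {"type": ["number", "null"], "minimum": 0}
            }
          }
        }
      }
    },
    "catheter": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "in_place": {"type": "boolean"},
        "removed_within_48h": {"type": "boolean"},
        "chronic": {"type": "boolean"}
      }
    },
    "cues": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "fever_temp_c": {"type": ["number", "null"], "minimum": 30, "maximum": 45},
        "fever_temp_f": {"type": ["number", "null"]},
        "new_onset_delirium": {"type": "boolean"},
        "rigors": {"type": "boolean"},
        "flank_pain": {"type": "boolean"},
        "acute_hematuria": {"type": "boolean"},
        "pelvic_discomfort": {"type": "boolean"},
        "urgency": {"type": "boolean"},
        "frequency": {"type": "boolean"},
        "dysuria": {"type": "boolean"},
        "suprapubic_pain": {"type": "boolean"},
        "pyuria": {"type": "boolean"},
        "foul_smelling_urine": {"type": "boolean"},
        "urine_color_change": {"type": "boolean"},
        "urine_sediment": {"type": "boolean"},
        "systemic_leukocytosis": {"type": "boolean"},
        "prior_uti_history": {"type": "boolean"},
        "resistant_organism": {"type": "boolean"},
        "vague_malaise": {"type": "boolean"},
        "weakness": {"type": "boolean"},
        "elderly_or_frail": {"type": "boolean"},
        "alternative_source": {
          "type": "object",
          "additionalProperties": {"type": "boolean"}
        }
      }
    }
  }
}
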