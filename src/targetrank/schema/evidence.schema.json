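{
  "$id": "targetrank/evidence/v1",
  "title": "Target-disease evidence record",
  "type": "object",
  "required": ["target_id", "disease_id", "datasource_id", "datatype_id", "score_payload"],
  "properties": {
    "target_id": {
      "type": "string",
      "pattern": "^ENSG[0-9]{11}$"
    },
    "disease_id": {
      "type": "string",
      "pattern": "^[A-Za-z][A-Za-z0-9]*_[0-9]+$"
    },
    "datasource_id": {
      "type": "string",
      "minLength": 1
    },
    "datatype_id": {
      "enum": [
        "genetic_association",
        "somatic_mutation",
        "known_drug",
        "affected_pathway",
        "rna_expression",
        "literature",
        "animal_model"
      ]
    },
    "score_payload": {
      "type": "object",
      "properties": {
        "resource_score": {"type": "number", "minimum": 0, "maximum": 1},
        "gwas_pvalue": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
        "priority_score": {"type": "number", "minimum": 0, "maximum": 100},
        "clinical_phase": {"type": "integer", "enum": [0, 1, 2, 3, 4]}
      }
    },
    "provenance": {
      "type": "object"
    }
  }
}
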