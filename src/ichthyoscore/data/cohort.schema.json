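{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "ichthyoscore cohort table",
 "description": "One object per patient with a nested biopsy array. Score cells use the semi-quantitative code grammar (−−/−/+/++/+++ grades, OK/PK keratinization, texture words, focal qualifiers); 'n.a.' marks non-assessable cells.",
 "type": "object",
 "required": ["schema_version", "patients"],
 "properties": {
  "schema_version": {"const": "ichthyoscore-cohort-1"},
  "provenance": {"type": "string"},
  "patients": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "sex", "diagnosis_group", "recorded_pattern", "biopsies"],
    "properties": {
     "id": {"type": "integer", "minimum": 1},
     "sex": {"enum": ["f", "m"]},
     "diagnosis_group": {"enum": ["IV", "XLI", "ARCI", "HARLEQUIN", "ADLI", "EI", "NTS", "PSD", "CHILD", "IFAP", "SAM", "MALT1", "KID", "SLS", "CHANARIN_DORFMAN", "CONRADI", "KIDAR"]},
     "gene": {"type": "string"},
     "flg_allele_count": {"enum": [0, 1, 2, null]},
     "genetically_confirmed": {"type": "boolean"},
     "clinical_features": {"type": "array", "items": {"type": "string"}},
     "recorded_pattern": {"enum": ["I", "II", "III", "IV", "V", "VI"]},
     "diagnosis_verbatim": {"type": "string"},
     "symptoms_verbatim": {"type": "string"},
     "biopsies": {
      "type": "array",
      "minItems": 1,
      "items": {
       "type": "object",
       "required": ["sc", "sg", "acanthosis", "inflammation"],
       "properties": {
        "sc": {"type": "string"},
        "sg": {"type": "string"},
        "acanthosis": {"type": "string"},
        "acanthosis_regularity": {"enum": ["regular", "irregular", "unspecified"]},
        "inflammation": {"type": "string"},
        "fhk": {"enum": ["present", "absent", "na"]},
        "ahk": {"enum": ["present", "absent", "na"]},
        "flags": {"type": "array", "items": {"type": "string"}},
        "site": {"type": "string"},
        "age_years": {"type": ["number", "null"]},
        "notes": {"type": "string"}
       }
      }
     }
    }
   }
  }
 }
}
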