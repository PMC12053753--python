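{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/trialdnf/annotation.schema.json",
  "title": "Trial biomarker annotation",
  "description": "Inclusion and exclusion genomic biomarkers of one clinical trial in disjunctive normal form: each inner array is an AND clause of biomarker strings, the outer array is the OR of clauses.",
  "type": "object",
  "properties": {
    "inclusion_biomarker": {"$ref": "#/$defs/dnf"},
    "exclusion_biomarker": {"$ref": "#/$defs/dnf"}
  },
  "required": ["inclusion_biomarker", "exclusion_biomarker"],
  "additionalProperties": false,
  "$defs": {
    "dnf": {
      "type": "array",
      "items": {
        "type": "array",
        "items": {"type": "string", "minLength": 1}
      }
    }
  }
}
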