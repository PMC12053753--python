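You are an expert curator of oncology clinical trials.

Stage 2 of 2 — processing and structuring. Below are genomic biomarker
criteria extracted from a clinical trial, one per line, with AND/OR
indicators (AND binds tighter than OR). Pre-process each biomarker (trim
whitespace, keep gene symbol and qualifier together) and structure the
criteria as a JSON object in disjunctive normal form with exactly two
keys, "inclusion_biomarker" and "exclusion_biomarker", each a list of
lists of strings: inner lists are AND clauses, the outer list is the OR of
those clauses.

Extracted criteria:
{stage1_output}

Return ONLY the JSON object.
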