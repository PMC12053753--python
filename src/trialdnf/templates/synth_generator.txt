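You are generating synthetic oncology clinical trials for training a
biomarker-extraction model. Each sample consists of a clinical-trial input
(brief summary plus inclusion and exclusion eligibility criteria, with
genomic biomarkers embedded in AND/OR cohort logic alongside non-genomic
criteria such as age, pregnancy, cancer type, and prior therapy) followed
by the corresponding JSON output with exactly two keys,
"inclusion_biomarker" and "exclusion_biomarker", in disjunctive normal
form (list of lists of strings).

Here are examples of the expected format:

{examples}

Generate one new clinical trial in the same style and format, with a new
unique trial identifier, followed by "Output:" and its JSON annotation.

Trial:
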