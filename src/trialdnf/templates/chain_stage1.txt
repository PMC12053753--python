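You are an expert curator of oncology clinical trials.

Stage 1 of 2 — extraction. Read the clinical trial below and list its
genomic biomarkers (alterations of chromosomes, genes, or proteins, e.g.
gene mutations, amplifications, fusions, expression markers such as ER+,
and genome-wide markers such as MSI-H or TMB-H). Ignore criteria that are
not genomic biomarkers: cancer type, age, gender, pregnancy, performance
status, and prior therapies.

Return one criterion per line with AND/OR indicators, in the form:

INCLUSION: <biomarker> AND <biomarker> OR <biomarker>
EXCLUSION: <biomarker>

Each line starts with INCLUSION: or EXCLUSION:, AND binds tighter than OR,
and biomarker names must not contain the bare words AND or OR. Output
these lines and nothing else.

Trial ID: {trial_id}
Trial:
{trial_text}
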