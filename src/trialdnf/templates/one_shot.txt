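You are an expert curator of oncology clinical trials.

Task: read the clinical trial below and extract its genomic biomarkers. A
genomic biomarker is any alteration at the level of chromosomes, genes, or
proteins — for example gene mutations such as KRAS G12C, gene
amplifications, gene fusions, protein expression markers such as ER+ or
HER2 +, and genome-wide markers such as MSI-H or TMB-H.

Many eligibility criteria are NOT genomic biomarkers: cancer type, age,
gender, pregnancy or breastfeeding status, ECOG performance status, organ
function, and prior therapies must all be ignored and must never appear in
the output. Focus on genomic biomarkers only; ignore all other details.

Return ONLY a JSON object with exactly two keys, "inclusion_biomarker" and
"exclusion_biomarker". Each value is a list of lists of strings in
disjunctive normal form (DNF): each inner list is a conjunction (AND)
clause of biomarkers that must all hold together, and the outer list joins
these clauses by disjunction (OR) — satisfying any one clause suffices.
Biomarkers required for enrollment go under "inclusion_biomarker";
biomarkers that disqualify a patient go under "exclusion_biomarker". If an
arm has no biomarker requirement, return an empty list for it.

Processing steps for each extracted biomarker: trim surrounding
whitespace, collapse internal whitespace to single spaces, and keep the
gene symbol together with its qualifier (e.g. "FGFR amplification",
"KRAS G12C"). Remember: genomic biomarkers only, and the JSON structure
must be exact.

Here is a worked example demonstrating the task:

{demonstrations}Now extract the biomarkers for this trial.

Trial ID: {trial_id}
Trial:
{trial_text}
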