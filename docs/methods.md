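# Methods

This note records the modelling and numerical choices behind `trialdnf`,
the assumptions they rest on, and what the synthetic test harness does and
does not demonstrate about real eligibility text.

## The DNF domain model

Biomarker logic is stored per arm as a disjunction of conjunction
clauses over normalized term strings. Canonicalization deduplicates terms
within a clause, drops empty clauses, deduplicates clauses under
set-equality, and sorts terms and clauses lexicographically by code
point, giving a deterministic serialization across platforms. Two
deliberate restrictions:

* **No logical minimization.** `[["A"], ["A", "B"]]` is left as two
  clauses even though the second is logically absorbed by the first.
  Structural scoring counts clauses as the annotator wrote them; applying
  absorption would silently change clause counts and therefore DNF-aware
  precision/recall. Equality between expressions is thus *syntactic
  canonical equality*, not Boolean equivalence.
* **Exact string matching after normalization.** Normalization trims and
  collapses whitespace but preserves case and symbols, because case and
  symbols carry meaning in biomarker names ("ER+" vs "er", "HER2 +" vs
  "HER2"). Synonym reconciliation ("ERBB2 mut" → "HER2 mutation") is
  available only through an explicit caller-supplied table; no table, no
  resolution. Ontology grounding (HGNC/HGVS) is a pluggable concern the
  package does not implement.

An empty DNF is legal and means the arm carries no biomarker constraint.
The wire format is strict: exactly the keys `inclusion_biomarker` and
`exclusion_biomarker`, each a list of lists of strings; a machine-readable
JSON Schema ships in `trialdnf/data/annotation.schema.json` for external
validators (the in-package check is hand-written and equivalent).

## Corpus curation

* **Keyword and lexicon screening** both use case-insensitive matching
  with word boundaries anchored on alphanumeric edges: "oncology" does
  not fire on "oncologist", "BRAF" does not fire inside "BRAFV600E", and
  symbol edges ("+" in "ER+") match literally. This prevents the gene
  short-name false positives that plain substring search produces.
* **Token outlier removal** uses the extreme Tukey fence, removing trials
  with token count above Q3 + 3·IQR, upper tail only. The extreme fence
  (3·IQR rather than 1.5) targets the rare pathologically long document
  while leaving ordinary long trials alone; short documents are never
  removed. The default token counter is whitespace word count, with any
  model tokenizer's length function accepted through the same contract.
  With fewer than four documents quartiles are meaningless, so the step
  becomes a logged no-op.
* **Splitting** shuffles with a seeded `random.Random` and takes
  `floor(f·n)` on the training side. The floor rule is load-bearing: it
  yields exactly 92/23 from 115 items and 156/39 from 195 at f = 0.8,
  the reference dataset sizes the preference-data pipeline reproduces.

## Lexicon vector screen

The published curation workflow used an embedding store whose model and
thresholds are unspecified; this package therefore defines an embedder
*contract* (deterministic text → fixed-length vector) and treats the
lexical screen as the reproducible baseline. The default embedder hashes
lower-cased character trigrams into 256 buckets with blake2b and
L2-normalizes the counts. It is deterministic and dependency-free but
purely lexical: it measures character-level overlap, not meaning, and
hash collisions can give small spurious similarities. Defaults
`top_k = 10`, `min_similarity = 0.1` are explicit but arbitrary; any
semantic embedder satisfying the contract can be swapped in.

## Prompting and parsing

Templates carry the task content as editable text assets: a task summary,
the definition of a genomic biomarker (chromosome-, gene-, or
protein-level alteration), the exact two-key DNF output format, an
instruction to ignore non-genomic criteria (age, pregnancy, cancer type,
prior therapy), deliberate repetition of the key instructions, and the
post-processing steps. Zero-/one-/two-shot variants differ only in the
number of worked demonstrations rendered before the query trial.

The chain strategy splits the task: stage 1 returns one criterion per
line in a small regular grammar (`INCLUSION:`/`EXCLUSION:` prefix, `AND`
binding tighter than `OR`, optional parentheses); stage 2 receives only
the stage-1 output and structures it into the final JSON. Passing only
the stage-1 output (not the original trial) follows the principle that
each chained prompt consumes its predecessor's output; the stage-2
builder is a separate function, so a caller who wants to include the
trial text can compose their own prompt. The line grammar is this
package's definition, chosen to be regular and robustly parseable.

All generation runs at temperature 0 and parse failures are data:
`run_extraction` converts backend exceptions, unbalanced output,
malformed JSON, and schema violations into failure outcomes that the
evaluator scores as empty predictions. JSON is recovered from prose-y
completions by a scanner that returns the first balanced top-level
`{...}` block while respecting string literals and escapes.

## Scoring

* Flat mode scores distinct terms; DNF mode scores canonical clauses with
  exact one-to-one matching and no partial credit. Exact clause matching
  is the strictest natural reading of "structured correctly in DNF"; a
  Jaccard partial-credit matcher exists behind a flag (default off) as a
  softer diagnostic.
* Aggregation defaults to micro (pool tp/fp/fn over trials, then compute
  P/R/F2); macro (average per-trial scores) is available. Degenerate
  conventions: all-zero counts — empty gold met by an empty prediction —
  score 1.0; a prediction against empty gold scores P = 0; an empty
  prediction against non-empty gold scores R = 0.
* Rounding to two decimals happens only at the presentation layer, half
  away from zero (`0.975 → 0.98`). Internal values are never rounded.

## Synthetic data generator

The generator emulates the cohort-structured shape of real eligibility
text: each inclusion clause renders as a cohort line ("Cohort A: tumor
must be ER+ with FGFR amplification"), separate cohorts express the
disjunction, exclusion clauses render as "Known X" lines, and 2–5
non-genomic distractor criteria (age, pregnancy, ECOG status, cancer
type, prior therapy, organ function) are interleaved. The rendering
vocabulary spans the biomarker surface forms that matter for
normalization: point mutations ("KRAS G12C"), amplifications, fusions,
losses, symbol-bearing expression markers ("ER+", "HER2 +", "PD-L1
positive") and genome-wide markers ("MSI-H", "TMB-H"). Defaults: 1–3
clauses per arm, 1–3 terms per clause, 30% of trials with no exclusion
biomarkers, seeded and fully deterministic per (seed, index).

What passing on this corpus shows: the pipeline's logic — parsing,
structure handling, scoring, failure accounting — is correct on text
whose gold is known by construction. What it does not show: performance
on real trials, whose phrasing is vastly more varied (negation,
cross-references, nested cohort tables, nomenclature drift). The
generator makes no claim of linguistic realism sufficient to benchmark an
LLM.

## Corruption model

`corrupt_prediction` simulates an imperfect extractor with stages applied
in a fixed order: whole-output parse failure; per-clause arm swap;
per-clause split into singletons; per-term drop; per-clause hallucinated
insertion. Two choices make the closed-form expectations exact:

* Term drops are decided **per distinct term per arm** — a dropped term
  vanishes from every clause containing it — so flat recall is a
  Binomial(n_distinct_gold_terms, 1 − p_drop) proportion with expectation
  exactly 1 − p_drop, independent of how terms repeat across clauses.
* Hallucinated terms come from a vocabulary disjoint from the generator's
  and are drawn without replacement within a trial, so every false
  positive is attributable and expected precision is
  E[kept]/(E[kept] + E[added]) with E[added] = one draw per gold clause
  at rate p_add. (This is a ratio of expectations; the Monte-Carlo tests
  use a 3σ-scale band around it.)

The closed form is defined only for the drop/add submodel; calling it
with swaps, splits, or parse failures enabled is an error rather than a
wrong number.

## DPO dataset and reference math

Preference pairs take the zero-shot prompt, the serialized gold as the
winning completion, and a deterministic backend's output as the losing
completion. Pairs where the backend already equals gold are retained but
flagged, leaving the filtering decision to the training code. Export is
text-level JSONL; tokenization and left-padding belong to whichever
tokenizer the training backend uses. The DPO loss is computed as
`log1p(exp(−βm))` via `logaddexp` for numerical stability at extreme
margins, and satisfies loss(m=0) = ln 2 exactly and the identity
loss(β, m) = loss(1, βm). The LoRA update returns W₀ + (α/r)·B·A and
reduces to W₀ under zero-initialized B. Gradient-based fine-tuning and
4-bit quantization are out of executable scope; the hyperparameters a
training run would use (β = 0.1, paged AdamW at lr 5e-5, 200 steps,
batch 8, LoRA rank 2 / α 4 / dropout 0.05, left padding) ship as a
config asset.

Synthetic-sample validation automates the machine-checkable part of a
human review: schema-valid JSON, every gold term present verbatim in the
generated text (case-insensitive), and a fresh trial id. Anything
subtler — clinical plausibility, unusual content — still needs a human,
which is why rejects are itemized with reasons rather than silently
dropped.

## Problem sizes

The test suite and examples run at deliberately modest scale — corpora of
20–115 trials for functional tests and 500 trials for parameter-recovery
checks — chosen so the binomial 3σ bands are tight enough to detect real
scoring bugs while the whole suite stays fast and deterministic.

## Known limitations

* Term matching is surface-level; two spellings of the same alteration
  are different terms unless a synonym table says otherwise.
* The hashing embedder is lexical, not semantic; the vector screen with
  the default embedder is a smoke-tested contract, not a retrieval
  benchmark.
* The bundled lexicon (`data/synthetic_lexicon.csv`) is a small synthetic
  stand-in for a curated variant-knowledgebase export, intended for tests
  and examples only.
* The intermediate chain grammar cannot express nested logic beyond one
  OR-of-ANDs level per line — which is exactly the DNF target, but means
  stage 1 cannot carry, e.g., negation.
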