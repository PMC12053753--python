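# trialdnf

Structure-then-match curation of genomic biomarkers in oncology
clinical-trial eligibility criteria.

Matching cancer patients to trials founders on the trials themselves:
eligibility criteria are free text, and their genomic requirements
("ER+ with FGFR amplification, or ER+ with HER2 +") mix nomenclature
variants with AND/OR cohort logic. `trialdnf` is a toolkit for the
*extraction* side of that problem. It curates trial corpora, drives
pluggable text-generation backends to extract inclusion and exclusion
biomarkers, represents each trial's biomarker logic in **disjunctive
normal form (DNF)**, and scores extractions against gold annotations. It
also builds preference datasets for fine-tuning an extractor with direct
preference optimization (DPO).

## The representation and the scores

A trial's biomarker logic per arm (inclusion / exclusion) is a DNF
formula encoded as a list of lists of strings:

```json
{"inclusion_biomarker": [["ER+", "FGFR amplification"], ["ER+", "HER2 +"]],
 "exclusion_biomarker": []}
```

Each inner list is a conjunction clause — all biomarkers must hold,
typically one trial cohort — and the outer list is the disjunction over
clauses. Extractions are scored per arm in two regimes:

* **flat** — the scoring unit is the distinct biomarker term; structure
  is ignored: tp = |G ∩ P|, fp = |P ∖ G|, fn = |G ∖ P| on the flattened
  term sets.
* **dnf** — the scoring unit is the canonical clause; a predicted clause
  counts only if its term set exactly matches a gold clause. A
  flat-perfect prediction can be DNF-wrong: gold `[["A","B"]]` vs
  prediction `[["A"],["B"]]` scores flat 2/0/0 but DNF 0/2/1.

Each regime reports precision P, recall R, and

F₂ = (1 + 2²) · P · R / (2² · P + R),

the F-beta score at β = 2, which weights recall twice as heavily as
precision — missing a biomarker costs a patient a match, while an extra
one only costs review time. Parse failures (completions from which no
schema-valid JSON can be recovered) are scored as empty predictions, so
unreliable extractors are penalized rather than dropped.

## Worked example

Generate a synthetic annotated corpus, simulate an imperfect extractor
with known error rates (30% term dropout, 10% hallucination rate per
clause, 20% clause splitting), and score it:

```python
import random
from trialdnf.synth import (TrialGenConfig, CorruptionConfig,
                            generate_corpus, corrupt_prediction)
from trialdnf.evaluation import evaluate_run, reports_to_frame

corpus = generate_corpus(TrialGenConfig(n_trials=50, seed=1))
cfg = CorruptionConfig(p_drop_term=0.3, p_add_term=0.1, p_split_clause=0.2)
rng = random.Random(1)
outcomes = [corrupt_prediction(a.gold, cfg, rng, trial_id=a.trial_id)
            for a in corpus]
print(reports_to_frame(evaluate_run(corpus, outcomes),
                       model="simulated-extractor",
                       strategy="zero_shot").to_string(index=False))
```

```
              model  strategy       arm mode aggregation  precision  recall   f2  n_trials  n_parse_failures
simulated-extractor zero_shot inclusion flat       micro       0.93    0.77 0.80        50                 0
simulated-extractor zero_shot exclusion flat       micro       0.96    0.65 0.70        50                 0
simulated-extractor zero_shot inclusion  dnf       micro       0.42    0.45 0.44        50                 0
simulated-extractor zero_shot exclusion  dnf       micro       0.51    0.46 0.47        50                 0
```

Reading the grid: flat recall ≈ 0.7 recovers the configured 30% dropout
(0.77 and 0.65 here bracket it at n=50); the much lower `dnf` rows show
how clause splitting destroys structural credit while leaving flat scores
intact. Replace the corruption model with a real backend (see
`trialdnf.backends.CallableBackend`) and `run_extraction` to score an
actual LLM the same way.

The same pipeline is available from the shell:

```bash
trialdnf synth --n 50 --seed 1 --out runs/synth
trialdnf curate --corpus runs/synth/corpus.jsonl \
    --lexicon "$(python -c 'import trialdnf; print(trialdnf.bundled_lexicon_path())')" \
    --out runs/curated
trialdnf extract --corpus runs/synth/corpus.jsonl \
    --annotations runs/synth/annotations.jsonl --backend mock-oracle \
    --strategy 0s --out runs/extract
trialdnf evaluate --corpus runs/synth/corpus.jsonl \
    --annotations runs/synth/annotations.jsonl \
    --outcomes runs/extract/outcomes.jsonl --out runs/eval
trialdnf prep-dpo --corpus runs/synth/corpus.jsonl \
    --annotations runs/synth/annotations.jsonl --backend mock-noisy \
    --out runs/dpo
```

Every command writes a `manifest.json` (inputs, config hash, seeds, stage
counts) sufficient to reproduce the run.

## DPO preference data and reference math

`trialdnf.preference` builds (prompt, chosen, rejected) triples — the
chosen completion is the serialized gold annotation, the rejected one is
a deterministic backend's actual output — and exports them as 80:20
train/validation JSONL (115 pairs → 92/23, 195 pairs → 156/39). The DPO
loss

−log σ(β·[(log π_θ(y_W|x) − log π_ref(y_W|x)) − (log π_θ(y_L|x) − log π_ref(y_L|x))])

and the LoRA low-rank update W₀ + (α/r)·B·A are implemented as verifiable
reference computations; training itself is a backend concern, and the
hyperparameters for one are shipped in
`trialdnf/data/dpo_hyperparameters.yaml`.

## Layout

| module | role |
| --- | --- |
| `trialdnf.dnf` | DNF domain model: parse, canonicalize, serialize, compare |
| `trialdnf.corpus` | corpus I/O, keyword filter, token outliers, seeded splits |
| `trialdnf.lexicon` | biomarker-lexicon screening (lexical + vector) |
| `trialdnf.prompting` | prompt templates, strategies, robust completion parsing |
| `trialdnf.backends` | oracle / scripted / noisy mocks and adapter hooks |
| `trialdnf.evaluation` | flat and DNF-aware P/R/F2, micro/macro aggregation |
| `trialdnf.preference` | DPO pairs, loss and LoRA reference math, synthetic augmentation |
| `trialdnf.synth` | synthetic annotated trials and the corruption model |
| `trialdnf.cli` | `trialdnf` console script tying the stages together |

See `docs/methods.md` for the modelling choices and their rationale.
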