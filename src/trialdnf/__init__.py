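"""trialdnf — structure-then-match curation of oncology trial biomarkers.

Extracts genomic inclusion/exclusion biomarkers from clinical-trial free
text through pluggable generation backends, represents them in
disjunctive normal form (a list of AND clauses joined by OR), and scores
extractions with flat and DNF-structure-aware precision/recall/F2. Also
constructs DPO preference datasets and provides reference implementations
of the DPO loss and the LoRA low-rank weight update.
"""

from importlib import resources

from .corpus import (
    AnnotatedTrial,
    SplitResult,
    TrialDocument,
    keyword_filter,
    read_annotations,
    read_trials,
    remove_token_outliers,
    split_dataset,
    token_lengths,
)
from .dnf import (
    DNFExpression,
    ExtractionError,
    ExtractionResult,
    ParseFailure,
    SchemaFailure,
    canonicalize,
    dnf_equal,
    dnf_from_lists,
    flatten_terms,
    normalize_term,
    parse_extraction_json,
    serialize,
)
from .evaluation import (
    MetricCounts,
    MetricReport,
    aggregate,
    evaluate_run,
    f_beta,
    score_dnf,
    score_flat,
    score_outcome,
)
from .lexicon import (
    BiomarkerLexicon,
    HashingEmbedder,
    ScreenReport,
    lexical_screen,
    load_lexicon,
    vector_screen,
)
from .preference import (
    DPOLossInputs,
    LoRAFactors,
    PreferencePair,
    build_preference_pairs,
    dpo_loss,
    dpo_loss_from_margin,
    export_dpo_dataset,
    generate_synthetic_annotated,
    lora_apply,
)
from .prompting import (
    ExtractionOutcome,
    build_prompt,
    extract_json_block,
    load_template,
    parse_intermediate,
    run_extraction,
)
from .synth import (
    CorruptionConfig,
    TrialGenConfig,
    corrupt_prediction,
    expected_flat_metrics,
    generate_corpus,
    generate_trial,
)

__version__ = "0.1.0"


def bundled_lexicon_path() -> str:
    """Path to the bundled synthetic fixture lexicon.

    A small synthetic stand-in for a CIViC-style biomarker name list, for
    tests and examples; real analyses should load their own lexicon.
    """
    return str(resources.files("trialdnf.data").joinpath("synthetic_lexicon.csv"))


def annotation_schema_path() -> str:
    """Path to the machine-readable JSON Schema of the annotation format."""
    return str(resources.files("trialdnf.data").joinpath("annotation.schema.json"))
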