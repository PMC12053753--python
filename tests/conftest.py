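import json

import pytest

from trialdnf.corpus import AnnotatedTrial, TrialDocument
from trialdnf.dnf import ExtractionResult, dnf_from_lists, parse_extraction_json
from trialdnf.synth import TrialGenConfig, generate_corpus

# The worked two-cohort example: eligibility requires ER+ with FGFR
# amplification (cohort 1) OR ER+ with HER2 + (cohort 2).
COHORT_EXAMPLE_JSON = json.dumps(
    {
        "inclusion_biomarker": [["ER+", "FGFR amplification"], ["ER+", "HER2 +"]],
        "exclusion_biomarker": [],
    }
)


@pytest.fixture
def cohort_example() -> ExtractionResult:
    return parse_extraction_json(COHORT_EXAMPLE_JSON)


@pytest.fixture
def cohort_trial(cohort_example) -> AnnotatedTrial:
    doc = TrialDocument(
        "NCT04092673",
        "A study of targeted therapy in ER+ metastatic breast cancer.",
        "Inclusion Criteria:\n"
        "- Cohort EMBF: tumor must be ER+ with FGFR amplification\n"
        "- Cohort EMBH: tumor must be ER+ and HER2 +\n"
        "- Age 18 years or older\n"
        "Exclusion Criteria:\n"
        "- Pregnant or breastfeeding\n",
    )
    return AnnotatedTrial(doc, cohort_example)


@pytest.fixture(scope="session")
def small_corpus() -> list[AnnotatedTrial]:
    return generate_corpus(TrialGenConfig(n_trials=20, seed=42))


def make_result(inclusion, exclusion=()) -> ExtractionResult:
    return ExtractionResult(dnf_from_lists(inclusion), dnf_from_lists(exclusion))
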