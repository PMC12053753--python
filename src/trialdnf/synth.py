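"""Synthetic annotated trials and a stochastic extractor-error model.

The generator emits eligibility text in the cohort-structured style real
oncology trials use: each inclusion cohort line conjoins its biomarkers
("ER+ with FGFR amplification"), separate cohorts are alternatives (the
OR), and non-genomic distractor criteria (age, pregnancy, ECOG status,
cancer type, prior therapy) are interleaved so that an extractor which
copies everything is measurably penalized. The gold annotation is, by
construction, exactly the DNF used to render the text.

The corruption model simulates an imperfect extractor with known error
rates so metric behaviour can be verified by parameter recovery: under
drop-only corruption, expected flat recall is exactly ``1 − p_drop_term``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .corpus import AnnotatedTrial, TrialDocument
from .dnf import (
    DNFExpression,
    ExtractionResult,
    canonicalize_result,
    flatten_terms,
    serialize,
)
from .prompting import ExtractionOutcome

__all__ = [
    "DEFAULT_VOCABULARY",
    "HALLUCINATION_VOCABULARY",
    "DISTRACTORS",
    "TrialGenConfig",
    "CorruptionConfig",
    "generate_trial",
    "generate_corpus",
    "corrupt_prediction",
    "expected_flat_metrics",
]

# (gene/marker, alteration) pairs spanning the surface forms that occur in
# trial criteria: point mutations, amplifications, fusions, expression
# markers with symbols, and genome-wide markers.
DEFAULT_VOCABULARY: tuple[tuple[str, str], ...] = (
    ("KRAS", "G12C"),
    ("BRAF", "V600E"),
    ("EGFR", "exon 19 deletion"),
    ("EGFR", "T790M"),
    ("PIK3CA", "H1047R"),
    ("IDH1", "R132H"),
    ("NRAS", "Q61K"),
    ("AKT1", "E17K"),
    ("FGFR", "amplification"),
    ("MET", "amplification"),
    ("HER2", "amplification"),
    ("MYC", "amplification"),
    ("CCND1", "amplification"),
    ("ALK", "fusion"),
    ("ROS1", "fusion"),
    ("RET", "fusion"),
    ("NTRK1", "fusion"),
    ("FGFR2", "fusion"),
    ("BRCA1", "mutation"),
    ("BRCA2", "mutation"),
    ("TP53", "mutation"),
    ("STK11", "mutation"),
    ("PTEN", "loss"),
    ("CDKN2A", "deletion"),
    ("ER", "+"),
    ("PR", "+"),
    ("HER2", "+"),
    ("PD-L1", "positive"),
    ("MSI-H", ""),
    ("TMB-H", ""),
)

# Disjoint from DEFAULT_VOCABULARY so every hallucinated false positive is
# attributable to the corruption model, never to the generator.
HALLUCINATION_VOCABULARY: tuple[str, ...] = (
    "SMARCA4 mutation",
    "ARID1A mutation",
    "CDK12 fusion",
    "KEAP1 mutation",
    "RB1 loss",
    "ATM mutation",
    "ERBB3 amplification",
    "GATA3 mutation",
    "MDM2 amplification",
    "NF1 mutation",
    "SETD2 mutation",
    "SMAD4 deletion",
)

DISTRACTORS: tuple[str, ...] = (
    "Age 18 years or older at the time of consent",
    "Not pregnant or breastfeeding",
    "ECOG performance status 0 or 1",
    "Histologically confirmed advanced solid malignancy",
    "No systemic chemotherapy within 4 weeks of enrollment",
    "Able to provide written informed consent",
    "Adequate hepatic and renal organ function",
    "No untreated or symptomatic brain metastases",
    "No prior treatment with an investigational agent within 30 days",
    "Life expectancy of at least 12 weeks",
)

CANCER_TYPES = (
    "non-small cell lung cancer",
    "metastatic breast cancer",
    "colorectal carcinoma",
    "advanced melanoma",
    "pancreatic adenocarcinoma",
    "urothelial carcinoma",
)


def _term(pair: tuple[str, str]) -> str:
    gene, alteration = pair
    return f"{gene} {alteration}".strip() if alteration else gene


@dataclass(frozen=True)
class TrialGenConfig:
    """Knobs of the synthetic-corpus generator.

    ``clauses_per_arm``/``terms_per_clause``/``n_distractors`` are inclusive
    (low, high) ranges sampled uniformly per trial. ``p_empty_exclusion``
    is the probability a trial has no exclusion biomarkers at all, which is
    common in real criteria.
    """

    n_trials: int = 50
    clauses_per_arm: tuple[int, int] = (1, 3)
    terms_per_clause: tuple[int, int] = (1, 3)
    p_empty_exclusion: float = 0.3
    n_distractors: tuple[int, int] = (2, 5)
    vocabulary: tuple[tuple[str, str], ...] = DEFAULT_VOCABULARY
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.clauses_per_arm, self.terms_per_clause):
            if not (1 <= lo <= hi):
                raise ValueError("ranges must be non-empty and positive")
        if not (0 <= self.n_distractors[0] <= self.n_distractors[1]):
            raise ValueError("n_distractors range invalid")
        if not (0.0 <= self.p_empty_exclusion <= 1.0):
            raise ValueError("p_empty_exclusion must lie in [0, 1]")


@dataclass(frozen=True)
class CorruptionConfig:
    """Stochastic error model for a simulated imperfect extractor.

    Stages apply in a fixed order: whole-output parse failure, per-clause
    arm swaps, per-clause splits into singletons, per-term drops, and
    per-clause hallucinated insertions from a vocabulary disjoint from the
    generator's.
    """

    p_drop_term: float = 0.0
    p_add_term: float = 0.0
    p_split_clause: float = 0.0
    p_swap_arm: float = 0.0
    p_parse_failure: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_drop_term", "p_add_term", "p_split_clause", "p_swap_arm", "p_parse_failure"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


def _sample_clauses(
    rng: random.Random,
    terms: list[str],
    n_clauses: int,
    terms_per_clause: tuple[int, int],
) -> list[tuple[str, ...]]:
    clauses = []
    for _ in range(n_clauses):
        k = rng.randint(*terms_per_clause)
        k = min(k, len(terms))
        clauses.append(tuple(rng.sample(terms, k)))
    return clauses


def _clause_phrase(clause: tuple[str, ...]) -> str:
    if len(clause) == 1:
        return clause[0]
    if len(clause) == 2:
        return f"{clause[0]} with {clause[1]}"
    return f"{clause[0]} with " + " and ".join(clause[1:])


def generate_trial(config: TrialGenConfig, index: int) -> AnnotatedTrial:
    """Generate one annotated trial, deterministic in (config.seed, index)."""
    rng = random.Random(f"{config.seed}:{index}")
    vocab = [_term(p) for p in config.vocabulary]
    max_terms = config.terms_per_clause[1]
    if len(vocab) < 2 * max_terms:
        raise ValueError("vocabulary too small for the configured clause sizes")

    n_inc = rng.randint(*config.clauses_per_arm)
    inc_clauses = _sample_clauses(rng, vocab, n_inc, config.terms_per_clause)
    inc_terms = {t for c in inc_clauses for t in c}
    exc_pool = [t for t in vocab if t not in inc_terms]
    if rng.random() < config.p_empty_exclusion or len(exc_pool) < max_terms:
        exc_clauses: list[tuple[str, ...]] = []
    else:
        n_exc = rng.randint(*config.clauses_per_arm)
        exc_clauses = _sample_clauses(rng, exc_pool, n_exc, config.terms_per_clause)

    cancer = rng.choice(CANCER_TYPES)
    trial_id = f"SYN-{config.seed}-{index:05d}"
    brief = (
        f"A phase {rng.randint(1, 3)} open-label study of targeted therapy in "
        f"participants with {cancer} harboring selected genomic alterations."
    )
    n_dist = rng.randint(*config.n_distractors)
    distractors = rng.sample(DISTRACTORS, min(n_dist, len(DISTRACTORS)))
    split_at = rng.randint(0, len(distractors))

    lines = ["Inclusion Criteria:"]
    lines += [f"- {d}" for d in distractors[:split_at]]
    for letter, clause in zip("ABCDEFGH", inc_clauses):
        lines.append(
            f"- Cohort {letter}: tumor must be {_clause_phrase(clause)}"
        )
    lines += [f"- {d}" for d in distractors[split_at:]]
    lines.append("Exclusion Criteria:")
    for clause in exc_clauses:
        lines.append(f"- Known {_clause_phrase(clause)}")
    lines.append("- Uncontrolled intercurrent illness")

    gold = ExtractionResult(
        DNFExpression(tuple(inc_clauses)), DNFExpression(tuple(exc_clauses))
    )
    doc = TrialDocument(trial_id, brief, "\n".join(lines))
    return AnnotatedTrial(doc, gold)


def generate_corpus(config: TrialGenConfig) -> list[AnnotatedTrial]:
    """Generate ``config.n_trials`` independent annotated trials."""
    return [generate_trial(config, i) for i in range(config.n_trials)]


def _corrupt_arm_pair(
    gold: ExtractionResult, config: CorruptionConfig, rng: random.Random
) -> ExtractionResult:
    arms: dict[str, list[tuple[str, ...]]] = {"inclusion": [], "exclusion": []}
    # stage 1: per-clause arm swaps
    for arm, other in (("inclusion", "exclusion"), ("exclusion", "inclusion")):
        for clause in gold.arm(arm).clauses:
            target = other if rng.random() < config.p_swap_arm else arm
            arms[target].append(tuple(clause))
    # stage 2: clause splits
    for arm in arms:
        split: list[tuple[str, ...]] = []
        for clause in arms[arm]:
            if len(clause) > 1 and rng.random() < config.p_split_clause:
                split.extend((t,) for t in clause)
            else:
                split.append(clause)
        arms[arm] = split
    # stage 3: per-distinct-term drops (a dropped term vanishes everywhere
    # in its arm, so flat recall is Binomial(n_terms, 1 - p_drop))
    for arm in arms:
        distinct = sorted({t for c in arms[arm] for t in c})
        dropped = {t for t in distinct if rng.random() < config.p_drop_term}
        arms[arm] = [
            tuple(t for t in c if t not in dropped) for c in arms[arm]
        ]
        arms[arm] = [c for c in arms[arm] if c]
    # stage 4: hallucinated insertions — one draw per original gold clause
    for arm in ("inclusion", "exclusion"):
        n_draws = len(gold.arm(arm).clauses)
        pool = [t for t in HALLUCINATION_VOCABULARY]
        rng.shuffle(pool)
        for _ in range(n_draws):
            if rng.random() < config.p_add_term and pool:
                term = pool.pop()
                if arms[arm]:
                    i = rng.randrange(len(arms[arm]))
                    arms[arm][i] = arms[arm][i] + (term,)
                else:
                    arms[arm].append((term,))
    return ExtractionResult(
        DNFExpression(tuple(arms["inclusion"])),
        DNFExpression(tuple(arms["exclusion"])),
    )


def corrupt_prediction(
    gold: ExtractionResult,
    config: CorruptionConfig,
    draw: random.Random | None = None,
    trial_id: str = "synthetic",
    strategy: str = "corrupted",
) -> ExtractionOutcome:
    """Simulate an imperfect extractor's output for one trial.

    With all probabilities zero the outcome equals the (canonicalized)
    gold. A parse-failure draw short-circuits everything and returns a
    failure outcome whose raw completion is unparseable text.
    """
    rng = draw if draw is not None else random.Random(config.seed)
    if rng.random() < config.p_parse_failure:
        return ExtractionOutcome(
            trial_id,
            strategy,
            "I could not find any biomarkers worth mentioning...",
            failure_reason="ParseFailure: simulated unparseable completion",
        )
    pred = canonicalize_result(_corrupt_arm_pair(gold, config, rng))
    return ExtractionOutcome(trial_id, strategy, serialize(pred), result=pred)


def expected_flat_metrics(
    config: CorruptionConfig, golds: Sequence[ExtractionResult]
) -> dict[str, tuple[float, float]]:
    """Closed-form expected flat (precision, recall) per arm.

    Defined only for the drop/add submodel (no parse failures, swaps, or
    splits). Expected recall is ``1 − p_drop_term``; expected precision is
    ``E[kept] / (E[kept] + E[added])`` with ``E[kept]`` the corpus's
    distinct-gold-term mass times the keep rate and ``E[added]`` one
    insertion draw per gold clause at rate ``p_add_term``.
    """
    if config.p_parse_failure or config.p_swap_arm or config.p_split_clause:
        raise ValueError(
            "closed form is defined only for the drop/add submodel "
            "(p_parse_failure = p_swap_arm = p_split_clause = 0)"
        )
    out = {}
    for arm in ("inclusion", "exclusion"):
        n_terms = sum(len(flatten_terms(g.arm(arm))) for g in golds)
        n_clauses = sum(len(g.arm(arm).clauses) for g in golds)
        kept = n_terms * (1.0 - config.p_drop_term)
        added = n_clauses * config.p_add_term
        recall = 1.0 - config.p_drop_term if n_terms else 1.0
        precision = kept / (kept + added) if kept + added > 0 else 1.0
        out[arm] = (precision, recall)
    return out
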