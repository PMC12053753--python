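"""Prompt assembly, backend invocation, and robust completion parsing.

Four extraction strategies are supported: zero-shot, one-shot, two-shot,
and a two-stage chain (stage 1 extracts biomarkers as AND/OR criterion
lines; stage 2 structures them into the final DNF JSON). Backends are
abstract — anything with a ``generate(prompt, temperature, max_tokens)``
method — and all generation runs at temperature 0 so that completions are
reproducible.

Parse failures are data, not exceptions: :func:`run_extraction` never lets
a backend or parsing error escape; it records a failure outcome that the
evaluator scores as an empty prediction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Protocol, Sequence

from .corpus import AnnotatedTrial, TrialDocument
from .dnf import (
    DNFExpression,
    ExtractionError,
    ExtractionResult,
    ParseFailure,
    dnf_from_lists,
    parse_extraction_json,
    serialize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PromptTemplate",
    "GenerationBackend",
    "ExtractionOutcome",
    "IntermediateCriteria",
    "STRATEGIES",
    "load_template",
    "build_prompt",
    "build_stage2_prompt",
    "build_synth_prompt",
    "extract_json_block",
    "parse_intermediate",
    "render_intermediate",
    "intermediate_to_result",
    "run_extraction",
]

TEMPLATE_NAMES = (
    "zero_shot",
    "one_shot",
    "two_shot",
    "chain_stage1",
    "chain_stage2",
    "synth_generator",
)
STRATEGIES = ("zero_shot", "one_shot", "two_shot", "chain")

_ARITY = {"zero_shot": 0, "one_shot": 1, "two_shot": 2, "chain_stage1": 0}


@dataclass(frozen=True)
class PromptTemplate:
    """A named prompt body with ``{placeholder}`` slots."""

    name: str
    body: str


class GenerationBackend(Protocol):
    """Contract for text-generation backends.

    At temperature 0 the same prompt must yield the same completion.
    """

    label: str

    def generate(
        self, prompt: str, temperature: float = 0.0, max_tokens: int = 1024
    ) -> str: ...


@dataclass
class ExtractionOutcome:
    """One extraction attempt: either a parsed result or a failure reason."""

    trial_id: str
    strategy: str
    raw_completion: str
    result: ExtractionResult | None = None
    failure_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.result is None) == (self.failure_reason is None):
            raise ValueError("exactly one of result / failure_reason must be set")

    @property
    def failed(self) -> bool:
        return self.failure_reason is not None


@dataclass(frozen=True)
class IntermediateCriteria:
    """Stage-1 chain output: per-arm criterion lines as DNF clause lists."""

    inclusion_lines: tuple[tuple[tuple[str, ...], ...], ...]
    exclusion_lines: tuple[tuple[tuple[str, ...], ...], ...]


def load_template(name: str) -> PromptTemplate:
    """Load a bundled prompt template asset by name."""
    if name not in TEMPLATE_NAMES:
        raise ValueError(f"unknown template {name!r}; expected one of {TEMPLATE_NAMES}")
    body = resources.files("trialdnf.templates").joinpath(f"{name}.txt").read_text()
    return PromptTemplate(name=name, body=body)


def _render_demo(demo: AnnotatedTrial) -> str:
    return (
        f"Example trial (ID {demo.trial_id}):\n"
        f"{demo.document.text}\n"
        f"Example output:\n{serialize(demo.gold)}\n\n"
    )


def build_prompt(
    template: PromptTemplate,
    trial: TrialDocument,
    demonstrations: Sequence[AnnotatedTrial] = (),
) -> str:
    """Render an extraction prompt: demonstrations (if any), then the trial.

    The number of demonstrations must match the template's arity (0 for
    zero-shot and chain stage 1, 1 for one-shot, 2 for two-shot). Rendering
    is deterministic; the trial text appears exactly once.
    """
    if template.name not in _ARITY:
        raise ValueError(f"template {template.name!r} is not an extraction template")
    arity = _ARITY[template.name]
    if len(demonstrations) != arity:
        raise ValueError(
            f"template {template.name!r} expects {arity} demonstration(s), "
            f"got {len(demonstrations)}"
        )
    demos = "".join(_render_demo(d) for d in demonstrations)
    return template.body.format(
        demonstrations=demos, trial_id=trial.trial_id, trial_text=trial.text
    )


def build_stage2_prompt(template: PromptTemplate, stage1_output: str) -> str:
    """Render the chain's second prompt around the stage-1 output.

    Stage 2 consumes only the stage-1 output, not the original trial text.
    """
    if template.name != "chain_stage2":
        raise ValueError("stage-2 rendering requires the chain_stage2 template")
    return template.body.format(stage1_output=stage1_output.strip())


def build_synth_prompt(
    template: PromptTemplate, seed_examples: Sequence[AnnotatedTrial]
) -> str:
    """Render the synthetic-trial generator prompt from seed examples."""
    if template.name != "synth_generator":
        raise ValueError("synthetic rendering requires the synth_generator template")
    if not seed_examples:
        raise ValueError("at least one seed example is required")
    blocks = [
        f"Trial ID: {ex.trial_id}\nTrial:\n{ex.document.text}\nOutput:\n{serialize(ex.gold)}"
        for ex in seed_examples
    ]
    return template.body.format(examples="\n\n".join(blocks))


def extract_json_block(text: str) -> str:
    """Return the first balanced top-level ``{...}`` block in ``text``.

    Scans left to right with a brace counter that respects JSON string
    literals and backslash escapes, so braces inside strings never
    terminate the block. Raises :class:`ParseFailure` if no balanced block
    exists.
    """
    start = text.find("{")
    while start != -1:
        depth = 0
        in_string = False
        escaped = False
        for i in range(start, len(text)):
            ch = text[i]
            if in_string:
                if escaped:
                    escaped = False
                elif ch == "\\":
                    escaped = True
                elif ch == '"':
                    in_string = False
            elif ch == '"':
                in_string = True
            elif ch == "{":
                depth += 1
            elif ch == "}":
                depth -= 1
                if depth == 0:
                    return text[start : i + 1]
        start = text.find("{", start + 1)
    raise ParseFailure("no balanced JSON object found in completion")


_ARM_LINE = re.compile(r"^\s*(INCLUSION|EXCLUSION)\s*:\s*(.+?)\s*$")
_RESERVED = re.compile(r"\b(?:AND|OR)\b")


def _parse_expr(expr: str, line_no: int) -> tuple[tuple[str, ...], ...]:
    clauses = []
    for clause_text in re.split(r"\s+OR\s+", expr):
        clause_text = clause_text.strip()
        if clause_text.startswith("(") and clause_text.endswith(")"):
            clause_text = clause_text[1:-1].strip()
        terms = []
        for term in re.split(r"\s+AND\s+", clause_text):
            term = term.strip()
            if not term or _RESERVED.search(term):
                raise ParseFailure(f"line {line_no}: malformed boolean expression")
            terms.append(term)
        clauses.append(tuple(terms))
    return tuple(clauses)


def parse_intermediate(text: str) -> IntermediateCriteria:
    """Parse stage-1 chain output under the line-oriented AND/OR grammar.

    Grammar: one criterion per line; ``line := ARM ":" expr`` with
    ``ARM ∈ {INCLUSION, EXCLUSION}``; ``expr := clause (" OR " clause)*``;
    ``clause := term (" AND " term)*``; optional parentheses around a
    clause. Terms may not contain the bare reserved tokens AND/OR. An
    unparseable line raises :class:`ParseFailure` naming the line.
    """
    inclusion, exclusion = [], []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        m = _ARM_LINE.match(line)
        if m is None:
            raise ParseFailure(f"line {line_no}: expected 'INCLUSION:' or 'EXCLUSION:' prefix")
        clauses = _parse_expr(m.group(2), line_no)
        (inclusion if m.group(1) == "INCLUSION" else exclusion).append(clauses)
    return IntermediateCriteria(tuple(inclusion), tuple(exclusion))


def intermediate_to_result(criteria: IntermediateCriteria) -> ExtractionResult:
    """Collapse stage-1 criterion lines into a single DNF per arm.

    Lines within an arm are alternatives, so their clause lists concatenate
    under the outer disjunction.
    """
    inc = [list(clause) for line in criteria.inclusion_lines for clause in line]
    exc = [list(clause) for line in criteria.exclusion_lines for clause in line]
    return ExtractionResult(dnf_from_lists(inc), dnf_from_lists(exc))


def _render_arm(expr: DNFExpression, arm: str) -> list[str]:
    if not expr:
        return []
    return [arm + ": " + " OR ".join(" AND ".join(clause) for clause in expr.clauses)]


def render_intermediate(result: ExtractionResult) -> str:
    """Render a result in the stage-1 AND/OR line format (inverse parser)."""
    lines = _render_arm(result.inclusion, "INCLUSION") + _render_arm(
        result.exclusion, "EXCLUSION"
    )
    return "\n".join(lines)


def _parse_completion(completion: str) -> ExtractionResult:
    return parse_extraction_json(extract_json_block(completion))


def run_extraction(
    trial: TrialDocument,
    strategy: str,
    backend: GenerationBackend,
    demonstrations: Sequence[AnnotatedTrial] = (),
    max_tokens: int = 1024,
) -> ExtractionOutcome:
    """Run one strategy on one trial and parse the completion.

    Non-chain strategies make a single backend call; the chain strategy
    runs stage 1 (AND/OR criterion lines), validates it under the
    intermediate grammar, and feeds the raw stage-1 output into stage 2.
    All calls use temperature 0. Backend exceptions and parse/schema
    failures become failure outcomes, never raised.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    raw = ""
    try:
        if strategy == "chain":
            stage1_prompt = build_prompt(load_template("chain_stage1"), trial)
            stage1_raw = backend.generate(stage1_prompt, temperature=0.0, max_tokens=max_tokens)
            raw = stage1_raw
            parse_intermediate(stage1_raw)  # validate before chaining
            stage2_prompt = build_stage2_prompt(load_template("chain_stage2"), stage1_raw)
            raw = backend.generate(stage2_prompt, temperature=0.0, max_tokens=max_tokens)
            result = _parse_completion(raw)
        else:
            prompt = build_prompt(load_template(strategy), trial, demonstrations)
            raw = backend.generate(prompt, temperature=0.0, max_tokens=max_tokens)
            result = _parse_completion(raw)
    except ExtractionError as exc:
        logger.debug("trial %s: %s: %s", trial.trial_id, type(exc).__name__, exc.reason)
        return ExtractionOutcome(
            trial.trial_id, strategy, raw,
            failure_reason=f"{type(exc).__name__}: {exc.reason}",
        )
    except Exception as exc:  # backend faults are data too
        logger.warning("trial %s: backend error: %s", trial.trial_id, exc)
        return ExtractionOutcome(
            trial.trial_id, strategy, raw, failure_reason=f"BackendError: {exc}"
        )
    return ExtractionOutcome(trial.trial_id, strategy, raw, result=result)
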