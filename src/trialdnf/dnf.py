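"""Disjunctive-normal-form model of trial biomarker criteria.

A trial's genomic eligibility logic is represented as a pair of DNF
expressions — one for inclusion biomarkers, one for exclusion biomarkers.
Each expression is a disjunction (OR) of conjunction clauses (AND), encoded
on the wire as a list of lists of strings under the two JSON keys
``"inclusion_biomarker"`` and ``"exclusion_biomarker"``. A clause is the
set of biomarkers a single cohort must jointly satisfy; the outer
disjunction says any one cohort's requirements suffice.

Equality here is *syntactic canonical equality*: clauses are unordered sets
of terms and the disjunction is an unordered collection of clauses, but no
Boolean minimization (absorption, implication) is performed — the structure
the annotator wrote is the structure that is scored.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ExtractionError",
    "ParseFailure",
    "SchemaFailure",
    "DNFExpression",
    "ExtractionResult",
    "normalize_term",
    "dnf_from_lists",
    "canonicalize",
    "canonicalize_result",
    "dnf_equal",
    "flatten_terms",
    "parse_extraction_json",
    "serialize",
]

INCLUSION_KEY = "inclusion_biomarker"
EXCLUSION_KEY = "exclusion_biomarker"


class ExtractionError(ValueError):
    """Base class for recoverable extraction-parsing errors.

    These are *data*, not crashes: the evaluator catches them and scores the
    offending completion as an empty prediction.
    """

    def __init__(self, reason: str) -> None:
        super().__init__(reason)
        self.reason = reason


class ParseFailure(ExtractionError):
    """The completion is not syntactically parseable (e.g. broken JSON)."""


class SchemaFailure(ExtractionError):
    """The completion parses but violates the two-key annotation schema."""


_WS = re.compile(r"\s+")


def normalize_term(raw: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Normalize a raw biomarker string to its canonical surface form.

    Trims leading/trailing whitespace and collapses internal runs of
    whitespace to single spaces; case and symbols (``+``, ``/``, ``-``) are
    preserved because they are semantically load-bearing in biomarker
    nomenclature ("ER+" vs "ER"). If a synonym table is supplied, the
    whitespace-normalized form is looked up in it and mapped to the
    preferred label; without a table no synonym resolution occurs.

    Raises
    ------
    ValueError
        If the term normalizes to the empty string.
    """
    if not isinstance(raw, str):
        raise SchemaFailure(f"biomarker term must be a string, got {type(raw).__name__}")
    term = _WS.sub(" ", raw.strip())
    if synonyms is not None:
        term = synonyms.get(term, term)
        term = _WS.sub(" ", term.strip())
    if not term:
        raise ValueError("biomarker term normalizes to the empty string")
    return term


@dataclass(frozen=True)
class DNFExpression:
    """A disjunction of conjunction clauses over biomarker terms.

    ``clauses`` is a tuple of clauses; each clause is a tuple of normalized
    term strings. An empty expression is legal and means "no biomarker
    constraint" for that arm.
    """

    clauses: tuple[tuple[str, ...], ...] = ()

    def __iter__(self) -> Iterator[tuple[str, ...]]:
        return iter(self.clauses)

    def __len__(self) -> int:
        return len(self.clauses)

    def __bool__(self) -> bool:
        return bool(self.clauses)

    def to_lists(self) -> list[list[str]]:
        return [list(clause) for clause in self.clauses]


@dataclass(frozen=True)
class ExtractionResult:
    """Inclusion and exclusion biomarker logic extracted from one trial."""

    inclusion: DNFExpression = field(default_factory=DNFExpression)
    exclusion: DNFExpression = field(default_factory=DNFExpression)

    def arm(self, name: str) -> DNFExpression:
        if name == "inclusion":
            return self.inclusion
        if name == "exclusion":
            return self.exclusion
        raise KeyError(f"unknown arm {name!r}")


def dnf_from_lists(
    lists: Iterable[Iterable[str]],
    synonyms: Mapping[str, str] | None = None,
) -> DNFExpression:
    """Build a :class:`DNFExpression` from a list-of-lists of raw terms."""
    clauses = []
    for clause in lists:
        clauses.append(tuple(normalize_term(t, synonyms) for t in clause))
    return DNFExpression(tuple(clauses))


def canonicalize(expr: DNFExpression) -> DNFExpression:
    """Return the canonical form of a DNF expression.

    Deduplicates terms within each clause, drops empty clauses, deduplicates
    clauses under set-equality of their terms, sorts terms lexicographically
    within each clause and clauses lexicographically by their sorted term
    tuples. Idempotent. Deliberately does NOT apply logical absorption:
    ``[["A"], ["A", "B"]]`` is already canonical even though the second
    clause is logically redundant, because structural scoring counts clauses
    as written.
    """
    seen: set[tuple[str, ...]] = set()
    for clause in expr.clauses:
        terms = tuple(sorted(set(clause)))
        if terms:
            seen.add(terms)
    return DNFExpression(tuple(sorted(seen)))


def canonicalize_result(result: ExtractionResult) -> ExtractionResult:
    return ExtractionResult(canonicalize(result.inclusion), canonicalize(result.exclusion))


def dnf_equal(a: DNFExpression, b: DNFExpression) -> bool:
    """Syntactic canonical equality (not full Boolean equivalence)."""
    return canonicalize(a) == canonicalize(b)


def flatten_terms(expr: DNFExpression) -> set[str]:
    """Union of all terms over all clauses — the 'flat' view of an arm."""
    return {term for clause in expr.clauses for term in clause}


def _check_arm(value: object, key: str) -> list[list[str]]:
    if not isinstance(value, list):
        raise SchemaFailure(f"value of {key!r} must be a list of lists")
    out: list[list[str]] = []
    for i, clause in enumerate(value):
        if not isinstance(clause, list):
            raise SchemaFailure(f"{key}[{i}] must be a list of strings, got {type(clause).__name__}")
        for j, term in enumerate(clause):
            if not isinstance(term, str):
                raise SchemaFailure(f"{key}[{i}][{j}] must be a string, got {type(term).__name__}")
        out.append(list(clause))
    return out


def parse_extraction_json(
    text: str,
    synonyms: Mapping[str, str] | None = None,
) -> ExtractionResult:
    """Parse annotation/model-output JSON into an :class:`ExtractionResult`.

    Strict schema: the top level must be an object with exactly the keys
    ``"inclusion_biomarker"`` and ``"exclusion_biomarker"``, each a list of
    lists of strings. Terms are normalized on the way in.

    Raises :class:`ParseFailure` on malformed JSON and :class:`SchemaFailure`
    on schema violations; both are catchable as :class:`ExtractionError`.
    """
    try:
        obj = json.loads(text)
    except (json.JSONDecodeError, TypeError) as exc:
        raise ParseFailure(f"malformed JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise SchemaFailure(f"top level must be a JSON object, got {type(obj).__name__}")
    expected = {INCLUSION_KEY, EXCLUSION_KEY}
    keys = set(obj)
    if keys != expected:
        missing = sorted(expected - keys)
        extra = sorted(keys - expected)
        parts = []
        if missing:
            parts.append(f"missing keys {missing}")
        if extra:
            parts.append(f"unexpected keys {extra}")
        raise SchemaFailure("; ".join(parts))
    try:
        inclusion = dnf_from_lists(_check_arm(obj[INCLUSION_KEY], INCLUSION_KEY), synonyms)
        exclusion = dnf_from_lists(_check_arm(obj[EXCLUSION_KEY], EXCLUSION_KEY), synonyms)
    except ValueError as exc:
        if isinstance(exc, ExtractionError):
            raise
        raise SchemaFailure(str(exc)) from exc
    return ExtractionResult(inclusion, exclusion)


def serialize(result: ExtractionResult) -> str:
    """Serialize to canonical annotation JSON.

    Expressions are canonicalized and keys emitted in fixed order (inclusion
    then exclusion) with standard single-space separators, so serialization
    is deterministic and ``parse(serialize(x))`` is the identity on
    canonical results.
    """
    canon = canonicalize_result(result)
    payload = {
        INCLUSION_KEY: canon.inclusion.to_lists(),
        EXCLUSION_KEY: canon.exclusion.to_lists(),
    }
    return json.dumps(payload, ensure_ascii=False, separators=(", ", ": "))
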