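"""Reading, filtering and splitting clinical-trial corpora.

A corpus is a list of :class:`TrialDocument` — the registry identifier plus
the two free-text sections used for biomarker extraction (brief summary and
eligibility criteria). Gold annotations live in a JSONL side-car keyed by
trial id. Curation steps: keyword screening for oncology relevance, token
length profiling with upper-tail outlier removal, and seeded train/test
splitting.
"""

from __future__ import annotations

import json
import logging
import math
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence, TypeVar

import numpy as np
import pandas as pd

from .dnf import (
    EXCLUSION_KEY,
    INCLUSION_KEY,
    ExtractionResult,
    dnf_from_lists,
    serialize,
)

logger = logging.getLogger(__name__)

T = TypeVar("T")

__all__ = [
    "CorpusError",
    "TrialDocument",
    "AnnotatedTrial",
    "SplitResult",
    "read_trials",
    "write_trials_jsonl",
    "read_annotations",
    "write_annotations_jsonl",
    "keyword_filter",
    "token_lengths",
    "remove_token_outliers",
    "token_length_table",
    "split_dataset",
]


class CorpusError(ValueError):
    """Raised for malformed corpus files or invalid curation arguments."""


@dataclass(frozen=True)
class TrialDocument:
    """One clinical trial: identifier plus the two analyzed text sections."""

    trial_id: str
    brief_summary: str = ""
    eligibility_text: str = ""

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise CorpusError("trial_id must be non-empty")
        if not (self.brief_summary or self.eligibility_text):
            raise CorpusError(f"trial {self.trial_id}: both text fields are empty")

    @property
    def text(self) -> str:
        """The concatenated free text searched by filters and screens."""
        return "\n".join(s for s in (self.brief_summary, self.eligibility_text) if s)


@dataclass(frozen=True)
class AnnotatedTrial:
    """A trial paired with its gold DNF annotation."""

    document: TrialDocument
    gold: ExtractionResult

    @property
    def trial_id(self) -> str:
        return self.document.trial_id


@dataclass(frozen=True)
class SplitResult:
    """A deterministic train/held-out partition of a dataset."""

    train: tuple
    held_out: tuple
    seed: int
    train_fraction: float


def _registry_record(rec: dict, index: int) -> TrialDocument:
    # Registry-export dialect: either the nested protocolSection layout of a
    # clinicaltrials.gov v2 study record, or flat registry field names.
    proto = rec.get("protocolSection")
    if isinstance(proto, dict):
        ident = proto.get("identificationModule", {}).get("nctId")
        summary = proto.get("descriptionModule", {}).get("briefSummary", "")
        criteria = proto.get("eligibilityModule", {}).get("eligibilityCriteria", "")
    else:
        ident = rec.get("nct_id") or rec.get("trial_id")
        summary = rec.get("brief_summary", "")
        criteria = rec.get("eligibility_criteria", rec.get("eligibility_text", ""))
    if not ident:
        raise CorpusError(f"record {index}: missing field 'trial_id'/'nctId'")
    return TrialDocument(ident, summary or "", criteria or "")


def read_trials(path: str | Path, format: str = "jsonl") -> list[TrialDocument]:
    """Read a trial corpus from disk.

    ``jsonl``: one object per line with keys ``trial_id``, ``brief_summary``,
    ``eligibility_text``. ``registry-json``: a JSON array (or an object with
    a ``studies`` key) of registry study records; the brief-summary and
    eligibility-criteria fields are routed into the two text fields.
    """
    path = Path(path)
    docs: list[TrialDocument] = []
    if format == "jsonl":
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"record {i}: invalid JSON ({exc})") from exc
            if "trial_id" not in rec or not rec["trial_id"]:
                raise CorpusError(f"record {i}: missing field 'trial_id'")
            try:
                docs.append(
                    TrialDocument(
                        rec["trial_id"],
                        rec.get("brief_summary", "") or "",
                        rec.get("eligibility_text", "") or "",
                    )
                )
            except CorpusError as exc:
                raise CorpusError(f"record {i}: {exc}") from exc
    elif format == "registry-json":
        payload = json.loads(path.read_text())
        records = payload.get("studies", payload) if isinstance(payload, dict) else payload
        if not isinstance(records, list):
            raise CorpusError("registry-json file must contain a list of study records")
        docs = [_registry_record(rec, i) for i, rec in enumerate(records)]
    else:
        raise CorpusError(f"unknown corpus format {format!r}")
    ids = [d.trial_id for d in docs]
    dupes = {t for t in ids if ids.count(t) > 1}
    if dupes:
        raise CorpusError(f"duplicate trial ids: {sorted(dupes)}")
    return docs


def write_trials_jsonl(trials: Iterable[TrialDocument], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trials:
            fh.write(
                json.dumps(
                    {
                        "trial_id": t.trial_id,
                        "brief_summary": t.brief_summary,
                        "eligibility_text": t.eligibility_text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_annotations(
    path: str | Path, trials: Sequence[TrialDocument]
) -> list[AnnotatedTrial]:
    """Join a JSONL annotation side-car onto a corpus by trial id.

    Each side-car line carries ``trial_id`` plus the two-key annotation
    object. Trials without an annotation are skipped; annotations without a
    matching trial raise.
    """
    by_id = {t.trial_id: t for t in trials}
    annotated: list[AnnotatedTrial] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        rec = json.loads(line)
        tid = rec.get("trial_id")
        if tid is None:
            raise CorpusError(f"annotation record {i}: missing field 'trial_id'")
        if tid not in by_id:
            raise CorpusError(f"annotation record {i}: unknown trial id {tid!r}")
        gold = ExtractionResult(
            dnf_from_lists(rec.get(INCLUSION_KEY, [])),
            dnf_from_lists(rec.get(EXCLUSION_KEY, [])),
        )
        annotated.append(AnnotatedTrial(by_id[tid], gold))
    return annotated


def write_annotations_jsonl(annotated: Iterable[AnnotatedTrial], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annotated:
            payload = json.loads(serialize(a.gold))
            payload = {"trial_id": a.trial_id, **payload}
            fh.write(json.dumps(payload, ensure_ascii=False) + "\n")


def _boundary_pattern(word: str) -> re.Pattern:
    # Anchors on alphanumeric edges so "oncology" does not fire on
    # "oncologist"; symbols inside the keyword match literally.
    return re.compile(
        rf"(?<![A-Za-z0-9]){re.escape(word)}(?![A-Za-z0-9])", re.IGNORECASE
    )


def keyword_filter(
    trials: Sequence[TrialDocument], keywords: Sequence[str]
) -> list[TrialDocument]:
    """Keep trials whose text contains at least one keyword.

    Matching is case-insensitive with word-boundary anchoring on
    alphanumeric edges.
    """
    if not keywords:
        raise CorpusError("keywords must be non-empty")
    patterns = [_boundary_pattern(k) for k in keywords]
    return [t for t in trials if any(p.search(t.text) for p in patterns)]


def token_lengths(
    trials: Sequence[TrialDocument],
    counter: Callable[[str], int] | None = None,
) -> list[int]:
    """Token count per trial, aligned by index.

    The default counter is whitespace word count; any callable mapping text
    to a non-negative integer (e.g. a model tokenizer's length function) can
    be substituted.
    """
    if counter is None:
        counter = lambda text: len(text.split())  # noqa: E731
    return [counter(t.text) for t in trials]


def remove_token_outliers(
    trials: Sequence[TrialDocument], counts: Sequence[int]
) -> tuple[list[TrialDocument], list[TrialDocument]]:
    """Drop trials with extreme upper-tail token counts.

    Uses the extreme Tukey fence: a trial is removed iff its count exceeds
    Q3 + 3·IQR. Only the upper tail is fenced — short trials are never
    removed. With fewer than four trials the quartiles are not meaningful,
    so nothing is removed and a warning is logged.
    """
    if len(counts) != len(trials):
        raise CorpusError("counts must align with trials")
    if len(trials) < 4:
        logger.warning("fewer than 4 trials; skipping outlier removal")
        return list(trials), []
    q1, q3 = np.percentile(np.asarray(counts, dtype=float), [25, 75])
    fence = q3 + 3.0 * (q3 - q1)
    kept, removed = [], []
    for trial, count in zip(trials, counts):
        (removed if count > fence else kept).append(trial)
    return kept, removed


def token_length_table(
    trials: Sequence[TrialDocument], counts: Sequence[int]
) -> pd.DataFrame:
    """Token-length report with outlier flags, exportable to CSV."""
    if len(trials) >= 4:
        q1, q3 = np.percentile(np.asarray(counts, dtype=float), [25, 75])
        fence = q3 + 3.0 * (q3 - q1)
    else:
        fence = math.inf
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "n_tokens": list(counts),
            "outlier_flag": [c > fence for c in counts],
        }
    )


def split_dataset(items: Sequence[T], train_fraction: float, seed: int) -> SplitResult:
    """Seeded shuffle-then-prefix split with floor on the training side.

    ``|train| = floor(train_fraction · n)``; the same seed always yields the
    same membership. This floor rule reproduces the reference splits
    115 → 92/23 and 195 → 156/39 at an 80:20 ratio.
    """
    n = len(items)
    if n < 2:
        raise CorpusError("need at least 2 items to split")
    if not (0.0 < train_fraction < 1.0):
        raise CorpusError("train_fraction must lie strictly between 0 and 1")
    order = list(range(n))
    random.Random(seed).shuffle(order)
    k = math.floor(train_fraction * n)
    train = tuple(items[i] for i in order[:k])
    held_out = tuple(items[i] for i in order[k:])
    return SplitResult(train, held_out, seed=seed, train_fraction=train_fraction)
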