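"""Biomarker-lexicon screening of trial corpora.

Screens a corpus for trials likely to carry genomic biomarkers using a
lexicon of biomarker names (e.g. CIViC-derived). Two routes are provided:
a deterministic lexical matcher (the reproducible baseline) and a
vector-similarity screen behind an embedder contract, whose default is a
deterministic character n-gram hashing embedder so no model download is
ever needed.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .corpus import TrialDocument
from .dnf import normalize_term

__all__ = [
    "LexiconError",
    "BiomarkerLexicon",
    "ScreenReport",
    "EmbedderContract",
    "HashingEmbedder",
    "load_lexicon",
    "lexical_screen",
    "vector_screen",
]

_HEADER_NAMES = {"term", "biomarker", "name", "biomarkers"}


class LexiconError(ValueError):
    """Raised for empty or malformed lexicon files."""


@dataclass(frozen=True)
class BiomarkerLexicon:
    """A deduplicated list of normalized biomarker names."""

    terms: tuple[str, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.terms:
            raise LexiconError("lexicon must contain at least one term")
        if len(set(self.terms)) != len(self.terms):
            raise LexiconError("lexicon terms must be unique after normalization")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class ScreenReport:
    """Which trials each biomarker matched, and by which method."""

    per_biomarker_hits: dict[str, set[str]]
    method: str

    @property
    def trial_ids(self) -> set[str]:
        out: set[str] = set()
        for hits in self.per_biomarker_hits.values():
            out |= hits
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "trial_ids": sorted(self.trial_ids),
            "per_biomarker_hits": {
                k: sorted(v) for k, v in sorted(self.per_biomarker_hits.items()) if v
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, ensure_ascii=False))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"biomarker": term, "trial_id": tid}
            for term, hits in sorted(self.per_biomarker_hits.items())
            for tid in sorted(hits)
        ]
        return pd.DataFrame(rows, columns=["biomarker", "trial_id"])


class EmbedderContract(Protocol):
    """Deterministic text embedder: same text must yield the same vector."""

    dim: int

    def embed(self, text: str) -> np.ndarray: ...


class HashingEmbedder:
    """Character n-gram hashing embedder.

    Maps each lower-cased character n-gram to a bucket via a stable hash
    (blake2b) and counts occurrences, then L2-normalizes. Fully
    deterministic across processes and platforms, which is what the screen's
    tests rely on; it is a bag-of-ngrams model, not a semantic one.
    """

    def __init__(self, dim: int = 256, ngram: int = 3) -> None:
        if dim < 1 or ngram < 1:
            raise ValueError("dim and ngram must be positive")
        self.dim = dim
        self.ngram = ngram

    def _bucket(self, gram: str) -> int:
        digest = hashlib.blake2b(gram.encode("utf-8"), digest_size=8).digest()
        return int.from_bytes(digest, "big") % self.dim

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=float)
        s = text.lower()
        n = self.ngram
        for i in range(max(len(s) - n + 1, 0)):
            vec[self._bucket(s[i : i + n])] += 1.0
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec


def load_lexicon(path: str | Path, source_label: str | None = None) -> BiomarkerLexicon:
    """Load a one-term-per-row CSV/TSV lexicon.

    A single leading header row named e.g. "term" or "biomarker" is skipped;
    rows are whitespace-normalized and deduplicated preserving first
    occurrence.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if lines and lines[0].lower() in _HEADER_NAMES:
        lines = lines[1:]
    terms: list[str] = []
    seen: set[str] = set()
    for ln in lines:
        term = normalize_term(ln)
        if term not in seen:
            seen.add(term)
            terms.append(term)
    if not terms:
        raise LexiconError(f"lexicon file {path} contains no terms")
    return BiomarkerLexicon(tuple(terms), source_label or path.name)


def _boundary_pattern(term: str) -> re.Pattern:
    # Word boundaries anchored on alphanumeric edges only: "BRAF" must not
    # fire inside "BRAFV600E", but symbol edges like the "+" of "ER+" match
    # literally with no boundary requirement beyond them.
    return re.compile(
        rf"(?<![A-Za-z0-9]){re.escape(term)}(?![A-Za-z0-9])", re.IGNORECASE
    )


def lexical_screen(
    trials: Sequence[TrialDocument], lexicon: BiomarkerLexicon
) -> ScreenReport:
    """Deterministic lexical screen: exact in-text biomarker mentions."""
    hits: dict[str, set[str]] = {term: set() for term in lexicon.terms}
    patterns = {term: _boundary_pattern(term) for term in lexicon.terms}
    for trial in trials:
        for term, pattern in patterns.items():
            if pattern.search(trial.text):
                hits[term].add(trial.trial_id)
    return ScreenReport(per_biomarker_hits=hits, method="lexical")


def vector_screen(
    trials: Sequence[TrialDocument],
    lexicon: BiomarkerLexicon,
    embedder: EmbedderContract | None = None,
    top_k: int = 10,
    min_similarity: float = 0.1,
) -> ScreenReport:
    """Similarity screen: rank trials by cosine similarity per biomarker.

    For each biomarker, trials are ranked by cosine similarity between the
    biomarker's embedding and the trial-text embedding; the top ``top_k``
    with similarity ≥ ``min_similarity`` are retained, and hits are unioned
    over biomarkers.
    """
    if top_k < 1:
        raise ValueError("top_k must be ≥ 1")
    if not (0.0 <= min_similarity <= 1.0):
        raise ValueError("min_similarity must lie in [0, 1]")
    if embedder is None:
        embedder = HashingEmbedder()
    trial_vecs = []
    for trial in trials:
        vec = np.asarray(embedder.embed(trial.text), dtype=float)
        if vec.shape != (embedder.dim,):
            raise ValueError(
                f"embedder returned shape {vec.shape}, expected ({embedder.dim},)"
            )
        trial_vecs.append(vec)
    hits: dict[str, set[str]] = {term: set() for term in lexicon.terms}
    for term in lexicon.terms:
        tvec = np.asarray(embedder.embed(term), dtype=float)
        if tvec.shape != (embedder.dim,):
            raise ValueError(
                f"embedder returned shape {tvec.shape}, expected ({embedder.dim},)"
            )
        sims = []
        for trial, vec in zip(trials, trial_vecs):
            denom = np.linalg.norm(tvec) * np.linalg.norm(vec)
            sim = float(tvec @ vec / denom) if denom > 0 else 0.0
            sims.append((sim, trial.trial_id))
        sims.sort(key=lambda pair: (-pair[0], pair[1]))
        for sim, tid in sims[:top_k]:
            if sim >= min_similarity and sim > 0:
                hits[term].add(tid)
    return ScreenReport(per_biomarker_hits=hits, method="vector")
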