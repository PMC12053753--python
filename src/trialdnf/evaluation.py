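"""Scoring of biomarker extractions: precision, recall, and F2.

Two regimes, per arm (inclusion / exclusion):

* **flat** — only the set of extracted biomarker terms matters; logical
  structure is ignored. The scoring unit is the distinct term.
* **dnf** — the scoring unit is the canonical conjunction clause; a
  predicted clause counts as a true positive only if its term set exactly
  equals some gold clause (one-to-one after canonical deduplication). An
  extraction can be flat-perfect yet DNF-wrong, e.g. gold ``[[A, B]]``
  against prediction ``[[A], [B]]``.

F2 (F-beta with β=2) weights recall twice as heavily as precision,
reflecting that missing a biomarker is costlier than over-extracting one
when matching patients to trials. Parse failures are scored as empty
predictions so unreliable extractors are penalized rather than excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .corpus import AnnotatedTrial
from .dnf import ExtractionResult, canonicalize, flatten_terms
from .prompting import ExtractionOutcome

__all__ = [
    "ARMS",
    "MODES",
    "MetricCounts",
    "MetricReport",
    "f_beta",
    "round_half_up",
    "score_flat",
    "score_dnf",
    "score_outcome",
    "aggregate",
    "evaluate_run",
    "reports_to_frame",
    "write_reports",
]

ARMS = ("inclusion", "exclusion")
MODES = ("flat", "dnf")

Arm = Literal["inclusion", "exclusion"]
Mode = Literal["flat", "dnf"]


@dataclass(frozen=True)
class MetricCounts:
    """True-positive / false-positive / false-negative tallies."""

    tp: float = 0
    fp: float = 0
    fn: float = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "MetricCounts") -> "MetricCounts":
        return MetricCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    """Precision/recall/F2 for one arm × mode cell of an evaluation grid."""

    arm: str
    mode: str
    aggregation: str
    precision: float
    recall: float
    f2: float
    n_trials: int
    n_parse_failures: int


def f_beta(precision: float, recall: float, beta: float = 2.0) -> float:
    """F-beta: ``(1 + β²)·P·R / (β²·P + R)``; 0 when both are 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision == 0.0 and recall == 0.0:
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * precision * recall / (b2 * precision + recall)


def round_half_up(x: float, places: int = 2) -> float:
    """Presentation rounding (half away from zero), e.g. 0.975 → 0.98."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _prf(counts: MetricCounts) -> tuple[float, float, float]:
    # All-zero counts mean empty gold and empty prediction: a vacuously
    # perfect extraction. Empty prediction against non-empty gold (or the
    # converse) scores zero on the undefined ratio.
    if counts.tp == counts.fp == counts.fn == 0:
        return 1.0, 1.0, 1.0
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else 0.0
    return p, r, f_beta(p, r, 2.0)


def score_flat(gold: ExtractionResult, pred: ExtractionResult) -> dict[str, MetricCounts]:
    """Term-set scoring per arm: tp = |G∩P|, fp = |P∖G|, fn = |G∖P|."""
    out = {}
    for arm in ARMS:
        g = flatten_terms(gold.arm(arm))
        p = flatten_terms(pred.arm(arm))
        out[arm] = MetricCounts(len(g & p), len(p - g), len(g - p))
    return out


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b) if a | b else 1.0


def score_dnf(
    gold: ExtractionResult,
    pred: ExtractionResult,
    partial_credit: bool = False,
) -> dict[str, MetricCounts]:
    """Clause-level scoring per arm.

    Default (strict): a predicted clause matches iff its canonical term set
    equals a gold clause; matching is one-to-one after both sides are
    canonically deduplicated. With ``partial_credit=True``, clauses are
    greedily paired by descending Jaccard overlap and each matched pair
    contributes its Jaccard to the tp mass (unmatched clauses are whole
    fp/fn) — an optional softer diagnostic, off by default.
    """
    out = {}
    for arm in ARMS:
        g = {frozenset(c) for c in canonicalize(gold.arm(arm)).clauses}
        p = {frozenset(c) for c in canonicalize(pred.arm(arm)).clauses}
        if not partial_credit:
            out[arm] = MetricCounts(len(g & p), len(p - g), len(g - p))
            continue
        pairs = sorted(
            ((_jaccard(gc, pc), sorted(gc), sorted(pc), gc, pc) for gc in g for pc in p),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        used_g: set[frozenset] = set()
        used_p: set[frozenset] = set()
        tp = 0.0
        for jac, _, _, gc, pc in pairs:
            if jac <= 0 or gc in used_g or pc in used_p:
                continue
            tp += jac
            used_g.add(gc)
            used_p.add(pc)
        out[arm] = MetricCounts(tp, len(p) - len(used_p), len(g) - len(used_g))
    return out


def _empty_result() -> ExtractionResult:
    return ExtractionResult()


def score_outcome(
    gold: ExtractionResult,
    outcome: ExtractionOutcome,
    mode: str,
    partial_credit: bool = False,
) -> dict[str, MetricCounts]:
    """Score one outcome; parse/backend failures count as empty predictions."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    pred = _empty_result() if outcome.failed else outcome.result
    if mode == "flat":
        return score_flat(gold, pred)
    return score_dnf(gold, pred, partial_credit=partial_credit)


def aggregate(
    counts: Sequence[MetricCounts], aggregation: str = "micro"
) -> tuple[float, float, float]:
    """Pool per-trial counts into (precision, recall, F2).

    ``micro`` sums tp/fp/fn over trials before computing ratios; ``macro``
    computes per-trial ratios (empty-vs-empty scores 1.0) and averages
    them. The two generally differ when per-trial gold sizes vary.
    """
    if not counts:
        raise ValueError("cannot aggregate an empty list of counts")
    if aggregation == "micro":
        total = MetricCounts()
        for c in counts:
            total = total + c
        return _prf(total)
    if aggregation == "macro":
        triples = [_prf(c) for c in counts]
        n = len(triples)
        return (
            sum(t[0] for t in triples) / n,
            sum(t[1] for t in triples) / n,
            sum(t[2] for t in triples) / n,
        )
    raise ValueError(f"unknown aggregation {aggregation!r}")


def evaluate_run(
    test_set: Sequence[AnnotatedTrial],
    outcomes: Sequence[ExtractionOutcome],
    aggregation: str = "micro",
    partial_credit: bool = False,
) -> list[MetricReport]:
    """Score an extraction run and emit the 2 (arm) × 2 (mode) metric grid.

    Outcomes are aligned to the test set by trial id; any mismatch in
    either direction is an error listing the offending ids.
    """
    if not outcomes:
        raise ValueError("no outcomes to evaluate")
    gold_by_id = {a.trial_id: a.gold for a in test_set}
    outcome_by_id = {o.trial_id: o for o in outcomes}
    missing = sorted(set(gold_by_id) - set(outcome_by_id))
    extra = sorted(set(outcome_by_id) - set(gold_by_id))
    if missing or extra:
        raise ValueError(
            f"trial-id mismatch: missing outcomes for {missing}, "
            f"outcomes without gold for {extra}"
        )
    n_failures = sum(1 for o in outcomes if o.failed)
    reports = []
    for mode in MODES:
        per_arm: dict[str, list[MetricCounts]] = {arm: [] for arm in ARMS}
        for trial_id, gold in gold_by_id.items():
            scored = score_outcome(
                gold, outcome_by_id[trial_id], mode, partial_credit=partial_credit
            )
            for arm in ARMS:
                per_arm[arm].append(scored[arm])
        for arm in ARMS:
            p, r, f2 = aggregate(per_arm[arm], aggregation)
            reports.append(
                MetricReport(
                    arm=arm,
                    mode=mode,
                    aggregation=aggregation,
                    precision=p,
                    recall=r,
                    f2=f2,
                    n_trials=len(gold_by_id),
                    n_parse_failures=n_failures,
                )
            )
    return reports


def reports_to_frame(
    reports: Iterable[MetricReport],
    model: str = "",
    strategy: str = "",
) -> pd.DataFrame:
    """Tabulate reports; ratios are rounded half-up to 2 d.p. here only."""
    rows = [
        {
            "model": model,
            "strategy": strategy,
            "arm": r.arm,
            "mode": r.mode,
            "aggregation": r.aggregation,
            "precision": round_half_up(r.precision),
            "recall": round_half_up(r.recall),
            "f2": round_half_up(r.f2),
            "n_trials": r.n_trials,
            "n_parse_failures": r.n_parse_failures,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def write_reports(
    reports: Sequence[MetricReport],
    out_dir: str | Path,
    model: str = "",
    strategy: str = "",
) -> None:
    """Write the metric grid as CSV and a JSON mirror (unrounded values)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = reports_to_frame(reports, model=model, strategy=strategy)
    frame.to_csv(out_dir / "metrics.csv", index=False)
    payload = [
        {
            "model": model,
            "strategy": strategy,
            **{k: getattr(r, k) for k in (
                "arm", "mode", "aggregation", "precision", "recall", "f2",
                "n_trials", "n_parse_failures",
            )},
        }
        for r in reports
    ]
    (out_dir / "metrics.json").write_text(json.dumps(payload, indent=2))
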