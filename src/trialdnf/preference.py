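"""Preference datasets for DPO fine-tuning, plus the reference math.

Direct preference optimization trains a policy to prefer a winning
completion y_W over a losing completion y_L given the same prompt x. Here
the winning completion is the serialized gold annotation and the losing
completion is what a deterministic (temperature-0) backend actually
produced for the same zero-shot prompt. The loss,

    L = −log σ(β·[(log π_θ(y_W|x) − log π_ref(y_W|x))
                 − (log π_θ(y_L|x) − log π_ref(y_L|x))]),

and the LoRA update ``W₀ + (α/r)·B·A`` are implemented as verifiable
reference computations; the actual gradient-based fine-tuning loop (a GPU
training concern) is out of scope, but the hyperparameters used by a
matching training run are shipped as a config asset.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .corpus import AnnotatedTrial, SplitResult, TrialDocument, split_dataset
from .dnf import ExtractionError, ExtractionResult, parse_extraction_json, serialize
from .prompting import (
    GenerationBackend,
    PromptTemplate,
    build_prompt,
    build_synth_prompt,
    extract_json_block,
    load_template,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PreferencePair",
    "PreferenceBuild",
    "DPOLossInputs",
    "LoRAFactors",
    "build_preference_pairs",
    "dpo_loss",
    "dpo_loss_from_margin",
    "lora_apply",
    "generate_synthetic_annotated",
    "export_dpo_dataset",
    "read_dpo_dataset",
    "load_finetune_config",
]


@dataclass(frozen=True)
class PreferencePair:
    """One DPO sample: prompt, winning (gold) and losing completions."""

    trial_id: str
    prompt: str
    chosen: str
    rejected: str

    @property
    def identical(self) -> bool:
        """True when the backend already produced the gold answer verbatim."""
        return self.chosen == self.rejected


@dataclass(frozen=True)
class PreferenceBuild:
    """Pairs plus an itemized log of trials skipped on backend failure."""

    pairs: tuple[PreferencePair, ...]
    skipped: tuple[tuple[str, str], ...]  # (trial_id, reason)


@dataclass(frozen=True)
class DPOLossInputs:
    """Log-probabilities of y_W and y_L under policy and reference models."""

    logp_policy_chosen: float
    logp_ref_chosen: float
    logp_policy_rejected: float
    logp_ref_rejected: float
    beta: float = 0.1

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        for name in (
            "logp_policy_chosen",
            "logp_ref_chosen",
            "logp_policy_rejected",
            "logp_ref_rejected",
        ):
            if getattr(self, name) > 0:
                raise ValueError(f"{name} is a log-probability and must be ≤ 0")

    @property
    def margin(self) -> float:
        """Preference margin: chosen log-ratio minus rejected log-ratio."""
        return (self.logp_policy_chosen - self.logp_ref_chosen) - (
            self.logp_policy_rejected - self.logp_ref_rejected
        )


@dataclass(frozen=True)
class LoRAFactors:
    """Low-rank update factors: W₀ (d×k), B (d×r), A (r×k), scale α."""

    w0: np.ndarray
    b: np.ndarray
    a: np.ndarray
    alpha: float
    r: int

    def __post_init__(self) -> None:
        w0, b, a = (np.asarray(m, dtype=float) for m in (self.w0, self.b, self.a))
        d, k = w0.shape
        if self.r > min(d, k):
            raise ValueError(f"rank {self.r} exceeds min(d, k) = {min(d, k)}")
        if b.shape != (d, self.r) or a.shape != (self.r, k):
            raise ValueError(
                f"shape mismatch: W0 {w0.shape}, B {b.shape}, A {a.shape}, r={self.r}"
            )


def build_preference_pairs(
    annotated: Sequence[AnnotatedTrial],
    backend: GenerationBackend,
    template: PromptTemplate | None = None,
) -> PreferenceBuild:
    """Build one preference pair per annotated trial.

    The prompt is the zero-shot extraction prompt, the chosen completion is
    the serialized gold, and the rejected completion is the backend's
    temperature-0 output for that prompt. Trials where the backend raises
    are skipped and itemized. Pairs whose rejected completion equals the
    gold are kept but carry ``identical=True`` so downstream training can
    filter them.
    """
    if template is None:
        template = load_template("zero_shot")
    pairs: list[PreferencePair] = []
    skipped: list[tuple[str, str]] = []
    for item in annotated:
        prompt = build_prompt(template, item.document)
        chosen = serialize(item.gold)
        try:
            rejected = backend.generate(prompt, temperature=0.0)
        except Exception as exc:
            logger.warning("trial %s: backend failed, pair skipped: %s", item.trial_id, exc)
            skipped.append((item.trial_id, str(exc)))
            continue
        pair = PreferencePair(item.trial_id, prompt, chosen, rejected)
        if pair.identical:
            logger.info("trial %s: rejected completion equals gold", item.trial_id)
        pairs.append(pair)
    return PreferenceBuild(tuple(pairs), tuple(skipped))


def dpo_loss(inputs: DPOLossInputs) -> float:
    """The DPO loss for one preference pair (natural-log scale).

    Numerically stable: ``−log σ(z) = log(1 + e^{−z})`` is evaluated via
    ``logaddexp`` so extreme margins neither overflow nor lose precision.
    At zero margin the loss is exactly ln 2 for any β.
    """
    return dpo_loss_from_margin(inputs.margin, inputs.beta)


def dpo_loss_from_margin(margin: float, beta: float) -> float:
    """DPO loss as a function of the preference margin and scale β."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return float(np.logaddexp(0.0, -beta * margin))


def lora_apply(factors: LoRAFactors) -> np.ndarray:
    """Effective weight after a low-rank update: ``W₀ + (α/r)·B·A``.

    With B = 0 (the standard initialization: Gaussian A, zero B) this is
    exactly W₀; with α = r the update is unscaled.
    """
    w0 = np.asarray(factors.w0, dtype=float)
    b = np.asarray(factors.b, dtype=float)
    a = np.asarray(factors.a, dtype=float)
    return w0 + (factors.alpha / factors.r) * (b @ a)


_CANDIDATE_ID = re.compile(r"^Trial ID:\s*(\S+)\s*$", re.MULTILINE)
_OUTPUT_SPLIT = re.compile(r"^Output:\s*$", re.MULTILINE)


@dataclass(frozen=True)
class RejectedCandidate:
    index: int
    reason: str
    text: str


def _parse_candidate(block: str, index: int) -> AnnotatedTrial:
    parts = _OUTPUT_SPLIT.split(block, maxsplit=1)
    if len(parts) != 2:
        raise ExtractionError(f"candidate {index}: no 'Output:' section")
    body, json_part = parts
    ids = _CANDIDATE_ID.findall(body)
    if not ids:
        raise ExtractionError(f"candidate {index}: no 'Trial ID:' line")
    trial_id = ids[0]
    text = _CANDIDATE_ID.sub("", body).strip()
    if not text:
        raise ExtractionError(f"candidate {index}: empty trial text")
    gold = parse_extraction_json(extract_json_block(json_part))
    return AnnotatedTrial(TrialDocument(trial_id, "", text), gold)


def generate_synthetic_annotated(
    generator_backend: GenerationBackend,
    seed_examples: Sequence[AnnotatedTrial],
    n: int,
    existing_ids: Sequence[str] = (),
    template: PromptTemplate | None = None,
) -> tuple[list[AnnotatedTrial], list[RejectedCandidate]]:
    """Request ``n`` synthetic annotated trials and validate each candidate.

    The generator prompt embeds the seed examples (manual gold by default)
    and ends with "Trial:" to elicit a new sample. Each candidate must
    satisfy three machine-checkable rules, the automatable core of a
    human quality review:

    (a) its JSON parses under the two-key annotation schema;
    (b) every gold biomarker term occurs in the generated trial text
        (case-insensitive substring);
    (c) its trial id collides with neither the corpus nor an earlier
        accepted candidate.

    Returns accepted trials and an itemized reject report.
    """
    if not seed_examples:
        raise ValueError("at least one seed example is required")
    if template is None:
        template = load_template("synth_generator")
    prompt = build_synth_prompt(template, seed_examples)
    taken = set(existing_ids) | {ex.trial_id for ex in seed_examples}
    accepted: list[AnnotatedTrial] = []
    rejected: list[RejectedCandidate] = []
    for i in range(n):
        try:
            block = generator_backend.generate(prompt, temperature=0.0)
        except Exception as exc:
            rejected.append(RejectedCandidate(i, f"generator error: {exc}", ""))
            continue
        try:
            candidate = _parse_candidate(block, i)
        except ExtractionError as exc:
            rejected.append(RejectedCandidate(i, f"schema: {exc.reason}", block))
            continue
        terms = {
            t
            for arm in ("inclusion", "exclusion")
            for clause in candidate.gold.arm(arm).clauses
            for t in clause
        }
        lowered = candidate.document.text.lower()
        missing = sorted(t for t in terms if t.lower() not in lowered)
        if missing:
            rejected.append(
                RejectedCandidate(i, f"terms absent from text: {missing}", block)
            )
            continue
        if candidate.trial_id in taken:
            rejected.append(
                RejectedCandidate(i, f"duplicate trial id {candidate.trial_id}", block)
            )
            continue
        taken.add(candidate.trial_id)
        accepted.append(candidate)
    return accepted, rejected


def export_dpo_dataset(
    pairs: Sequence[PreferencePair],
    out_dir: str | Path,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitResult:
    """Split pairs 80:20 and write train/validation JSONL files.

    Each line carries ``prompt``, ``chosen``, ``rejected`` (plus
    ``trial_id`` for auditability). 115 pairs yield 92/23 lines; 195 pairs
    yield 156/39.
    """
    if not pairs:
        raise ValueError("no pairs to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    split = split_dataset(list(pairs), train_fraction, seed)
    for name, subset in (("train", split.train), ("validation", split.held_out)):
        with open(out_dir / f"{name}.jsonl", "w") as fh:
            for p in subset:
                fh.write(
                    json.dumps(
                        {
                            "prompt": p.prompt,
                            "chosen": p.chosen,
                            "rejected": p.rejected,
                            "trial_id": p.trial_id,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    return split


def read_dpo_dataset(path: str | Path) -> list[PreferencePair]:
    """Read one exported DPO JSONL file back into preference pairs."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        pairs.append(
            PreferencePair(
                rec.get("trial_id", ""), rec["prompt"], rec["chosen"], rec["rejected"]
            )
        )
    return pairs


def load_finetune_config() -> dict:
    """Hyperparameters for a DPO/QLoRA training run attached downstream."""
    text = resources.files("trialdnf.data").joinpath("dpo_hyperparameters.yaml").read_text()
    return yaml.safe_load(text)
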