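"""Generation backends for extraction, testing, and dataset construction.

All backends satisfy the :class:`~trialdnf.prompting.GenerationBackend`
contract: ``generate(prompt, temperature, max_tokens) -> str``, with
determinism at temperature 0.

The oracle backend answers every prompt from the gold annotations and is
the closure test for the whole pipeline: running any strategy through it
must recover gold exactly. The noisy backend wraps the corruption model of
:mod:`trialdnf.synth` to emulate an imperfect extractor with known error
rates. Remote-API and local-model adapters are deliberately just hook
points — this package ships no network or model-inference code.
"""

from __future__ import annotations

import random
import re
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .corpus import AnnotatedTrial
from .dnf import ExtractionResult, serialize
from .prompting import (
    _ARM_LINE,
    intermediate_to_result,
    parse_intermediate,
    render_intermediate,
)

__all__ = [
    "OracleBackend",
    "ScriptedBackend",
    "FlakyBackend",
    "NoisyBackend",
    "CallableBackend",
    "make_backend",
]

_TRIAL_ID = re.compile(r"^Trial ID:\s*(\S+)\s*$", re.MULTILINE)
_STAGE1_MARKER = "Return one criterion per line with AND/OR indicators"
_STAGE2_MARKER = "Extracted criteria:"


def _trial_id_from_prompt(prompt: str) -> str:
    ids = _TRIAL_ID.findall(prompt)
    if not ids:
        raise ValueError("prompt carries no 'Trial ID:' line")
    return ids[-1]  # demonstrations precede the query trial


class OracleBackend:
    """Answers prompts perfectly from a gold-annotation table.

    For extraction prompts it returns the serialized gold annotation of the
    trial named in the prompt's final ``Trial ID:`` line. For chain
    stage 1 it renders the gold DNF as AND/OR criterion lines; for chain
    stage 2 it deterministically structures the criterion lines embedded in
    the prompt (no gold lookup — stage 2 is a pure transformation).
    """

    label = "mock-oracle"

    def __init__(self, annotated: Iterable[AnnotatedTrial]) -> None:
        self._gold: dict[str, ExtractionResult] = {
            a.trial_id: a.gold for a in annotated
        }

    def generate(
        self, prompt: str, temperature: float = 0.0, max_tokens: int = 1024
    ) -> str:
        if _STAGE2_MARKER in prompt:
            lines = [ln for ln in prompt.splitlines() if _ARM_LINE.match(ln)]
            criteria = parse_intermediate("\n".join(lines))
            return serialize(intermediate_to_result(criteria))
        gold = self._gold[_trial_id_from_prompt(prompt)]
        if _STAGE1_MARKER in prompt:
            return render_intermediate(gold)
        return serialize(gold)


class ScriptedBackend:
    """Replays a fixed queue (or trial-id map) of completions."""

    label = "scripted"

    def __init__(
        self,
        completions: Sequence[str] | Mapping[str, str],
    ) -> None:
        if isinstance(completions, Mapping):
            self._by_id: Mapping[str, str] | None = dict(completions)
            self._queue: list[str] = []
        else:
            self._by_id = None
            self._queue = list(completions)
        self._cursor = 0

    def generate(
        self, prompt: str, temperature: float = 0.0, max_tokens: int = 1024
    ) -> str:
        if self._by_id is not None:
            return self._by_id[_trial_id_from_prompt(prompt)]
        if self._cursor >= len(self._queue):
            raise RuntimeError("scripted backend exhausted its completions")
        out = self._queue[self._cursor]
        self._cursor += 1
        return out


@dataclass
class FlakyBackend:
    """Wraps a backend and raises on a configured set of trial ids."""

    inner: object
    fail_ids: frozenset[str] = field(default_factory=frozenset)
    label: str = "flaky"

    def generate(
        self, prompt: str, temperature: float = 0.0, max_tokens: int = 1024
    ) -> str:
        if _trial_id_from_prompt(prompt) in self.fail_ids:
            raise RuntimeError("simulated backend outage")
        return self.inner.generate(prompt, temperature=temperature, max_tokens=max_tokens)


class NoisyBackend:
    """Emulates an imperfect extractor with a known stochastic error model.

    Corrupts the gold annotation of the prompted trial using
    :func:`trialdnf.synth.corrupt_prediction`. The corruption draw is
    seeded from ``(seed, trial_id)``, so the backend honours the
    temperature-0 determinism contract: the same prompt always produces
    the same completion.
    """

    label = "mock-noisy"

    def __init__(
        self,
        annotated: Iterable[AnnotatedTrial],
        corruption,  # CorruptionConfig; imported lazily to avoid a cycle
        seed: int = 0,
    ) -> None:
        self._gold = {a.trial_id: a.gold for a in annotated}
        self._corruption = corruption
        self._seed = seed

    def generate(
        self, prompt: str, temperature: float = 0.0, max_tokens: int = 1024
    ) -> str:
        from .synth import corrupt_prediction

        trial_id = _trial_id_from_prompt(prompt)
        draw = random.Random(f"{self._seed}:{zlib.crc32(trial_id.encode())}")
        outcome = corrupt_prediction(
            self._gold[trial_id], self._corruption, draw, trial_id=trial_id
        )
        return outcome.raw_completion


@dataclass
class CallableBackend:
    """Adapter for any user-supplied generation callable.

    This is the hook point for remote APIs or local model servers: supply a
    function ``(prompt, temperature, max_tokens) -> str`` and a label.
    """

    fn: Callable[[str, float, int], str]
    label: str = "callable"

    def generate(
        self, prompt: str, temperature: float = 0.0, max_tokens: int = 1024
    ) -> str:
        return self.fn(prompt, temperature, max_tokens)


def make_backend(
    name: str,
    annotated: Sequence[AnnotatedTrial] = (),
    corruption=None,
    seed: int = 0,
):
    """Construct a backend from a config key.

    ``mock-oracle`` and ``mock-noisy`` require gold annotations;
    ``openai``/``local`` are adapter points — attach a real client through
    :class:`CallableBackend` instead of a config key.
    """
    if name == "mock-oracle":
        if not annotated:
            raise ValueError("mock-oracle backend requires gold annotations")
        return OracleBackend(annotated)
    if name == "mock-noisy":
        if not annotated:
            raise ValueError("mock-noisy backend requires gold annotations")
        if corruption is None:
            from .synth import CorruptionConfig

            corruption = CorruptionConfig(p_drop_term=0.2, p_add_term=0.1)
        return NoisyBackend(annotated, corruption, seed=seed)
    if name in {"openai", "local"}:
        raise ValueError(
            f"backend {name!r} is an adapter point: wrap your client in "
            "trialdnf.backends.CallableBackend and pass it directly"
        )
    raise ValueError(f"unknown backend {name!r}")
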