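"""Generation contract and record/replay backends.

Evaluation never needs model weights: a backend is anything with a
``generate_raw(model_id, prompt, doc_id, variation) -> str`` method.  The
replay backend serves stored generations from a JSONL file so that scoring
runs are reproducible; the simulator backend (:mod:`clinner.synthetic`)
produces parameterized synthetic generations.  Refusals and empty outputs
are ordinary records — downstream stages score them as-is, which is how
refusal behaviour legitimately lowers recall.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

logger = logging.getLogger(__name__)


@dataclass
class LLMOutput:
    """One raw generation tied to (document, model, prompt variation)."""

    doc_id: str
    model_id: str
    variation: int
    raw: str
    meta: dict = field(default_factory=dict)

    def key(self) -> tuple[str, str, int]:
        return (self.doc_id, self.model_id, self.variation)


class Backend(Protocol):
    def generate_raw(
        self, model_id: str, prompt: str, doc_id: str, variation: int
    ) -> str: ...


class ReplayBackend:
    """Serve generations recorded in a previous run.

    Missing (doc, model, variation) keys yield an empty generation with a
    ``missing`` meta flag rather than an error, so partial runs still score.
    """

    def __init__(self, outputs: Iterable[LLMOutput]):
        self._store: dict[tuple[str, str, int], LLMOutput] = {}
        for out in outputs:
            if out.key() in self._store:
                logger.warning("duplicate stored output for %s", out.key())
            self._store[out.key()] = out

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "ReplayBackend":
        return cls(load_outputs(path))

    def generate_raw(
        self, model_id: str, prompt: str, doc_id: str, variation: int
    ) -> str:
        out = self._store.get((doc_id, model_id, variation))
        if out is None:
            return ""
        return out.raw

    def has(self, doc_id: str, model_id: str, variation: int) -> bool:
        return (doc_id, model_id, variation) in self._store


class BackendRegistry:
    """model_id -> backend dispatch used by :func:`generate`."""

    def __init__(self) -> None:
        self._backends: dict[str, Backend] = {}

    def register(self, model_id: str, backend: Backend) -> None:
        self._backends[model_id] = backend

    def get(self, model_id: str) -> Backend:
        if model_id not in self._backends:
            raise KeyError(f"no backend registered for model {model_id!r}")
        return self._backends[model_id]


def generate(
    registry: BackendRegistry,
    model_id: str,
    prompt: str,
    doc_id: str,
    variation: int,
) -> LLMOutput:
    """Run one generation through the registered backend.

    Never raises on empty or refusal text; backend failures are recorded in
    ``meta`` and yield an empty ``raw``.
    """
    backend = registry.get(model_id)
    meta: dict = {}
    try:
        raw = backend.generate_raw(model_id, prompt, doc_id, variation)
    except Exception as exc:  # backend fault is data, not a crash
        logger.error("backend error for %s/%s/v%d: %s", model_id, doc_id, variation, exc)
        raw, meta = "", {"error": str(exc)}
    if isinstance(backend, ReplayBackend) and not backend.has(
        doc_id, model_id, variation
    ):
        meta["missing"] = True
    return LLMOutput(doc_id, model_id, variation, raw, meta)


# ---------------------------------------------------------------------------
# JSONL persistence (schema: doc_id, model_id, variation, raw, meta)


def save_outputs(outputs: Iterable[LLMOutput], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for out in outputs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": out.doc_id,
                        "model_id": out.model_id,
                        "variation": out.variation,
                        "raw": out.raw,
                        "meta": out.meta,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def load_outputs(path: str | Path) -> list[LLMOutput]:
    """Load a JSONL run; malformed lines are skipped with a warning count."""
    outputs: list[LLMOutput] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                outputs.append(
                    LLMOutput(
                        doc_id=obj["doc_id"],
                        model_id=obj["model_id"],
                        variation=int(obj["variation"]),
                        raw=obj["raw"],
                        meta=obj.get("meta") or {},
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                skipped += 1
                logger.warning("%s:%d: malformed JSONL line skipped", path, lineno)
    if skipped:
        logger.warning("%s: %d malformed lines skipped", path, skipped)
    return outputs
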