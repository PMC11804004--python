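"""Strict-grammar reference parsers.

These accept only the exact output structures the prompts request — the
canonical keyed-list dictionary and standard JSON with an ``annotations``
array — and reject everything else.  They share only the category
canonicalization and per-category case-insensitive deduplication with the
lenient parsers, and are used as independent oracles: on input they accept,
the lenient parsers must return the identical entity sets.
"""

from __future__ import annotations

import json
import re

from .parsing import (
    CATEGORIES,
    EMPTY,
    PARSED,
    ParsedEntitySet,
    canonicalize_category,
)


class StrictParseError(ValueError):
    """Input does not conform to the strict grammar."""


_STRICT_KEYED_RE = re.compile(
    r"\{\s*diseases\s*:\s*\[(?P<d>[^\[\]{}]*)\]\s*,"
    r"\s*symptoms\s*:\s*\[(?P<s>[^\[\]{}]*)\]\s*,"
    r"\s*medical procedures\s*:\s*\[(?P<p>[^\[\]{}]*)\]\s*\}\s*",
    re.IGNORECASE,
)


def strict_parse_keyed_list(
    raw: str, doc_id: str = "", variation: int = 2
) -> ParsedEntitySet:
    """Parse the canonical keyed-list structure; semicolon-delimited items."""
    m = _STRICT_KEYED_RE.fullmatch(raw.strip())
    if m is None:
        raise StrictParseError("not a canonical keyed-list structure")
    p = ParsedEntitySet(doc_id=doc_id, variation=variation)
    for group, cat in (("d", "DISEASE"), ("s", "SYMPTOM"), ("p", "PROCEDURE")):
        items = [it.strip() for it in m.group(group).split(";")]
        p.entities[cat] = _dedup([it for it in items if it])
    p.status = PARSED if p.total_entities() > 0 else EMPTY
    return p


def strict_parse_json_annotations(
    raw: str, doc_id: str = "", variation: int = 3
) -> ParsedEntitySet:
    """Parse standard JSON: object with an ``annotations`` array of
    ``{"entity": ..., "category": ...}`` objects; canonical categories only."""
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise StrictParseError(f"invalid JSON: {exc.msg}") from exc
    if not isinstance(data, dict) or not isinstance(data.get("annotations"), list):
        raise StrictParseError("missing annotations array")
    p = ParsedEntitySet(doc_id=doc_id, variation=variation)
    for obj in data["annotations"]:
        if not isinstance(obj, dict):
            raise StrictParseError("annotation is not an object")
        entity = str(obj.get("entity", "")).strip()
        cat = canonicalize_category(obj.get("category"))
        if not entity or cat is None:
            p.diagnostics.append(f"dropped: {obj!r}")
            continue
        p.entities[cat].append(entity)
    for cat in CATEGORIES:
        p.entities[cat] = _dedup(p.entities[cat])
    p.status = PARSED if p.total_entities() > 0 else EMPTY
    return p


def _dedup(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for it in items:
        key = it.casefold()
        if key not in seen:
            seen.add(key)
            out.append(it)
    return out
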