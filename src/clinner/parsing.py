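"""Fault-tolerant recovery of entity lists from raw LLM generations.

Prompt variation 2 asks for a Python-dictionary-like keyed list
(``{diseases: [...], symptoms: [...], medical procedures: [...]}``) and
variation 3 for a JSON ``annotations`` array.  Real generations deviate
freely: bullets instead of brackets, unquoted keys and values, missing
categories, truncated structures, prose wrapped around the payload, or
outright refusals.  The parsers here never raise on arbitrary input; they
extract what is recoverable, canonicalize category labels, and report a
parse status plus diagnostics.  On strictly valid input they agree exactly
with the strict-grammar parsers in :mod:`clinner.parsing_strict`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

CATEGORIES = ("DISEASE", "SYMPTOM", "PROCEDURE")

PARSED, EMPTY, UNPARSEABLE = "PARSED", "EMPTY", "UNPARSEABLE"

_CATEGORY_ALIASES = {
    "disease": "DISEASE",
    "diseases": "DISEASE",
    "symptom": "SYMPTOM",
    "symptoms": "SYMPTOM",
    "medical procedure": "PROCEDURE",
    "medical procedures": "PROCEDURE",
    "procedure": "PROCEDURE",
    "procedures": "PROCEDURE",
}


def canonicalize_category(label: str | None) -> str | None:
    """Map a free-form category label onto the three canonical categories.

    Case-insensitive and singular/plural-insensitive; separators are
    collapsed.  Anything unrecognized (e.g. "not applicable") maps to None.
    """
    if label is None:
        return None
    key = re.sub(r"[\s_\-]+", " ", str(label)).strip().lower()
    return _CATEGORY_ALIASES.get(key)


@dataclass
class ParsedEntitySet:
    """Per-category entity strings recovered from one generation."""

    doc_id: str
    variation: int
    entities: dict[str, list[str]] = field(
        default_factory=lambda: {c: [] for c in CATEGORIES}
    )
    status: str = EMPTY
    diagnostics: list[str] = field(default_factory=list)

    def total_entities(self) -> int:
        return sum(len(v) for v in self.entities.values())


def parsed_ok(p: ParsedEntitySet) -> bool:
    """True iff the generation yielded at least one canonical entity."""
    return p.status == PARSED


def _finalize(p: ParsedEntitySet, unparseable: bool = False) -> ParsedEntitySet:
    for cat in CATEGORIES:
        seen: set[str] = set()
        deduped = []
        for item in p.entities[cat]:
            key = item.casefold()
            if key not in seen:
                seen.add(key)
                deduped.append(item)
        p.entities[cat] = deduped
    if unparseable:
        p.status = UNPARSEABLE
    else:
        p.status = PARSED if p.total_entities() > 0 else EMPTY
    return p


def _clean_item(item: str) -> str:
    item = item.strip()
    item = re.sub(r"^[\-\*•·]+\s*", "", item)  # leading bullets
    item = re.sub(r"^\d+[.)]\s*", "", item)  # leading enumeration
    item = item.strip().strip("\"'“”‘’").strip()
    item = re.sub(r"[.;,:]+$", "", item).strip()
    return item


def _split_items(blob: str) -> list[str]:
    """Split a list body on semicolons, or commas outside round brackets."""
    if ";" in blob:
        parts = blob.split(";")
    else:
        parts, depth, buf = [], 0, []
        for ch in blob:
            if ch in "([{":
                depth += 1
            elif ch in ")]}":
                depth = max(0, depth - 1)
            if ch == "," and depth == 0:
                parts.append("".join(buf))
                buf = []
            else:
                buf.append(ch)
        parts.append("".join(buf))
    return [c for c in (_clean_item(p) for p in parts) if c]


_KEYWORD_RE = re.compile(
    r"(diseases?|symptoms?|medical[\s_\-]+procedures?|procedures?)"
    r"\s*[\"'“”]?\s*[:=]",
    re.IGNORECASE,
)

_BULLET_LINE_RE = re.compile(r"^\s*(?:[\-\*•·]|\d+[.)])\s*(.+)$")


def parse_keyed_list(raw: str, doc_id: str = "", variation: int = 2) -> ParsedEntitySet:
    """Recover entities from a keyed-list (variation 2) generation.

    Locates category keywords (with or without braces, bullets or
    asterisks), then reads the following bracketed or line-delimited list.
    Items are split on semicolons, or on commas outside round brackets, and
    trimmed of quotes, bullets and trailing punctuation.
    """
    p = ParsedEntitySet(doc_id=doc_id, variation=variation)
    if not raw or not raw.strip():
        p.diagnostics.append("empty generation")
        return _finalize(p, unparseable=True)
    matches = list(_KEYWORD_RE.finditer(raw))
    if not matches:
        p.diagnostics.append("no category keyword structure found")
        return _finalize(p, unparseable=True)
    for idx, m in enumerate(matches):
        cat = canonicalize_category(m.group(1))
        if cat is None:  # unreachable: regex only matches aliases
            continue
        region_end = matches[idx + 1].start() if idx + 1 < len(matches) else len(raw)
        region = raw[m.end():region_end]
        items = _parse_region(region, p.diagnostics)
        p.entities[cat].extend(items)
    return _finalize(p)


def _parse_region(region: str, diagnostics: list[str]) -> list[str]:
    stripped = region.lstrip()
    if stripped.startswith("["):
        open_at = region.index("[")
        close_at = region.find("]", open_at + 1)
        if close_at == -1:
            diagnostics.append("unterminated bracket list")
            body = region[open_at + 1 :]
        else:
            body = region[open_at + 1 : close_at]
        return _split_items(body)
    bullet_items = []
    for line in region.splitlines():
        bm = _BULLET_LINE_RE.match(line)
        if bm:
            bullet_items.append(bm.group(1))
    if bullet_items:
        diagnostics.append("bulleted list without brackets")
        return [c for c in (_clean_item(b) for b in bullet_items) if c]
    # inline, unbracketed list: read to end of line
    first_line = stripped.splitlines()[0] if stripped else ""
    first_line = first_line.rstrip("}").rstrip()
    return _split_items(first_line)


# ---------------------------------------------------------------------------
# JSON annotations (variation 3)


def parse_json_annotations(
    raw: str, doc_id: str = "", variation: int = 3
) -> ParsedEntitySet:
    """Recover entities from a JSON-annotations (variation 3) generation.

    Extracts the first brace-balanced (possibly truncated) region containing
    an ``annotations`` key, repairs common dialect faults — unquoted keys
    and values, single or typographic quotes, trailing commas, unterminated
    brackets — and reads objects with ``entity``/``category`` fields.
    Objects with a missing entity or a non-canonical category are dropped
    into diagnostics, never reassigned.
    """
    p = ParsedEntitySet(doc_id=doc_id, variation=variation)
    if not raw or not raw.strip():
        p.diagnostics.append("empty generation")
        return _finalize(p, unparseable=True)
    region = _extract_json_region(raw)
    if region is None:
        p.diagnostics.append("no JSON-like region found")
        return _finalize(p, unparseable=True)
    repaired = repair_json(region)
    try:
        data = json.loads(repaired)
    except json.JSONDecodeError as exc:
        p.diagnostics.append(f"unrecoverable JSON: {exc.msg}")
        return _finalize(p, unparseable=True)
    annotations = _find_annotations(data)
    if annotations is None:
        p.diagnostics.append("no annotations array in JSON")
        return _finalize(p, unparseable=True)
    for obj in annotations:
        if not isinstance(obj, dict):
            p.diagnostics.append(f"non-object annotation: {obj!r}")
            continue
        entity = obj.get("entity") or obj.get("Entity")
        entity = str(entity).strip() if entity is not None else ""
        cat = canonicalize_category(
            obj.get("category") if "category" in obj else obj.get("Category")
        )
        if not entity:
            p.diagnostics.append(f"annotation missing entity: {obj!r}")
            continue
        if cat is None:
            reason = (
                "non-canonical category"
                if ("category" in obj or "Category" in obj)
                else "missing category"
            )
            p.diagnostics.append(f"annotation with {reason} dropped: {obj!r}")
            continue
        cleaned = _clean_item(entity)
        if cleaned:
            p.entities[cat].append(cleaned)
    return _finalize(p)


def _extract_json_region(raw: str) -> str | None:
    """First brace-balanced region containing an annotations key, else the
    first balanced region, else the truncated tail from the first brace."""
    anchor = re.search(r"[\"'“]?annotations[\"'”]?\s*:", raw, re.IGNORECASE)
    if anchor:
        start = raw.rfind("{", 0, anchor.start())
        if start == -1:
            start = anchor.start()  # bare key without object wrapper
    else:
        start = raw.find("{")
        if start == -1:
            return None
    depth = 0
    in_str: str | None = None
    i = start
    while i < len(raw):
        ch = raw[i]
        if in_str:
            if ch == "\\":
                i += 2
                continue
            if ch == in_str or (in_str in "“”" and ch in "“”"):
                in_str = None
        elif ch in "\"'“":
            in_str = ch
        elif ch in "{[":
            depth += 1
        elif ch in "}]":
            depth -= 1
            if depth <= 0:
                return raw[start : i + 1]
        i += 1
    return raw[start:]  # truncated structure


_NUMBER_RE = re.compile(r"-?\d+(\.\d+)?([eE][+-]?\d+)?$")
_OPEN_QUOTES = "\"'“‘"
_CLOSERS = {"{": "}", "[": "]"}


def repair_json(text: str) -> str:
    """Best-effort repair of JSON-like text into standard JSON.

    Passes: normalize single/typographic quotes, quote bare keys and
    values, drop trailing commas, close unterminated strings and brackets.
    Valid JSON passes through unchanged (modulo nothing: every pass is a
    no-op on conforming input).
    """
    out: list[str] = []
    stack: list[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            out.append(ch)
            i += 1
        elif ch in _OPEN_QUOTES:
            i = _consume_string(text, i, out)
        elif ch in "{[":
            stack.append(ch)
            out.append(ch)
            i += 1
        elif ch in "}]":
            _strip_dangling(out)
            if stack and _CLOSERS[stack[-1]] == ch:
                stack.pop()
            out.append(ch)
            i += 1
        elif ch in ":,":
            out.append(ch)
            i += 1
        else:
            j = i
            while j < n and text[j] not in "{}[],:\"'“”":
                j += 1
            if j == i:  # stray closing quote with no opener: drop it
                i += 1
                continue
            token = text[i:j].strip()
            if token in ("true", "false", "null") or _NUMBER_RE.match(token):
                out.append(token)
            elif token:
                out.append(json.dumps(token, ensure_ascii=False))
            i = j
    _strip_dangling(out)
    while stack:
        out.append(_CLOSERS[stack.pop()])
    return "".join(out)


def _consume_string(text: str, i: int, out: list[str]) -> int:
    quote = text[i]
    close = {"'": "'", '"': '"', "“": "”", "‘": "’"}[quote]
    buf: list[str] = []
    i += 1
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "\\" and i + 1 < n:
            nxt = text[i + 1]
            if nxt == "u" and i + 6 <= n:
                try:
                    buf.append(chr(int(text[i + 2 : i + 6], 16)))
                    i += 6
                    continue
                except ValueError:
                    pass
            buf.append(
                {"n": "\n", "t": "\t", "r": "\r", "b": "\b", "f": "\f"}.get(nxt, nxt)
            )
            i += 2
            continue
        if ch == close or (quote == "“" and ch in "“”"):
            i += 1
            break
        buf.append(ch)
        i += 1
    out.append(json.dumps("".join(buf), ensure_ascii=False))
    return i


def _strip_dangling(out: list[str]) -> None:
    """Remove a trailing comma, or complete a dangling ``key:`` with null."""
    k = len(out) - 1
    while k >= 0 and out[k].isspace():
        k -= 1
    if k >= 0 and out[k] == ",":
        del out[k]
    elif k >= 0 and out[k] == ":":
        out.append("null")


def _find_annotations(data) -> list | None:
    if isinstance(data, list):
        return data
    if isinstance(data, dict):
        for key, value in data.items():
            if str(key).strip().lower() == "annotations" and isinstance(value, list):
                return value
        for value in data.values():  # nested one level down
            found = _find_annotations(value) if isinstance(value, dict) else None
            if found is not None:
                return found
    return None


def parse_output(raw: str, variation: int, doc_id: str = "") -> ParsedEntitySet:
    """Dispatch to the parser for the requested output structure (2 or 3)."""
    if variation == 2:
        return parse_keyed_list(raw, doc_id=doc_id, variation=2)
    if variation == 3:
        return parse_json_annotations(raw, doc_id=doc_id, variation=3)
    raise ValueError(f"structured parsing applies to variations 2 and 3, not {variation}")


# ---------------------------------------------------------------------------
# canonical re-serialization (round-trip support; also used by the simulator)


def to_keyed_list(p: ParsedEntitySet) -> str:
    """Render entities in the canonical variation-2 keyed-list format."""
    def body(cat: str) -> str:
        return "; ".join(p.entities[cat])

    return (
        "{diseases: [" + body("DISEASE") + "], symptoms: [" + body("SYMPTOM")
        + "], medical procedures: [" + body("PROCEDURE") + "]}"
    )


def to_json_annotations(p: ParsedEntitySet) -> str:
    """Render entities in the canonical variation-3 JSON format."""
    names = {"DISEASE": "disease", "SYMPTOM": "symptom", "PROCEDURE": "medical procedure"}
    annotations = [
        {"entity": ent, "category": names[cat]}
        for cat in CATEGORIES
        for ent in p.entities[cat]
    ]
    return json.dumps({"annotations": annotations}, ensure_ascii=False)
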