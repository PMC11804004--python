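"""Aligning model-emitted entity strings back onto the source document.

Both evaluation strategies reduce to the same primitive: decide whether a
term occurs — completely or partially — in some text, and then tag every
occurrence of the matched surface in the clinical case document with B/I
labels.  Matching is case-insensitive and whitespace-normalized at token
boundaries; there is no stemming or fuzzy edit-distance matching, so an
entity string the model hallucinated (absent from the document) can never
alter the tag sequence.  This grounding in the document text is what drives
the uniformly high precision of free-text outputs: the evaluator only ever
tags spans that really occur.

A *partial* match is a contiguous subsequence of the term's tokens of
length >= ceil(n/2) containing at least one non-stopword token; only the
matched subsequence is tagged in the document (tagging the unmatched tokens
would fabricate evidence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .corpus import (
    CATEGORY_PRIORITY,
    ClinicalDocument,
    EntityMention,
    IOBSequence,
    to_iob,
)

NONE, PARTIAL, COMPLETE = "NONE", "PARTIAL", "COMPLETE"

#: small fixed English stopword list; configurable per call
STOPWORDS = frozenset(
    """a an and are as at be but by for from in into is it of on or that the
    their then there these this to was were will with""".split()
)

_EDGE_PUNCT = ".,;:!?()[]{}\"'`“”‘’«»*#"


@dataclass(frozen=True)
class MatchResult:
    """Outcome of looking for a term in a text.

    ``matched_tokens`` holds the normalized token subsequence that was
    found: the full term for COMPLETE, a proper contiguous subsequence for
    PARTIAL, and None for NONE.
    """

    kind: str
    matched_tokens: tuple[str, ...] | None = None

    @property
    def matched_surface(self) -> str | None:
        return " ".join(self.matched_tokens) if self.matched_tokens else None


def normalize(text: str) -> tuple[str, list[tuple[int, int]]]:
    """Casefold, collapse whitespace, strip edge punctuation per token.

    Returns the normalized string and a per-character offset map: entry i is
    the raw ``(start, end)`` span that produced normalized character i
    (separator spaces map to the gap between the adjacent raw tokens).
    """
    norm_chars: list[str] = []
    offmap: list[tuple[int, int]] = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace():
            j += 1
        k, t = i, j
        while k < t and text[k] in _EDGE_PUNCT:
            k += 1
        while t > k and text[t - 1] in _EDGE_PUNCT:
            t -= 1
        if k < t:
            if norm_chars:
                norm_chars.append(" ")
                offmap.append((k, k))
            for p in range(k, t):
                for ch in text[p].casefold():  # casefold may expand (ß -> ss)
                    norm_chars.append(ch)
                    offmap.append((p, p + 1))
        i = j
    return "".join(norm_chars), offmap


def _norm_tokens(text: str) -> list[str]:
    norm, _ = normalize(text)
    return norm.split(" ") if norm else []


def _find_token_subsequence(
    haystack_tokens: Sequence[str], needle_tokens: Sequence[str]
) -> int:
    """Index of the first occurrence of needle as a contiguous token run."""
    n, m = len(haystack_tokens), len(needle_tokens)
    if m == 0 or m > n:
        return -1
    for i in range(n - m + 1):
        if list(haystack_tokens[i : i + m]) == list(needle_tokens):
            return i
    return -1


def match_term_in_text(
    term: str, text: str, stopwords: frozenset[str] = STOPWORDS
) -> MatchResult:
    """COMPLETE, PARTIAL or NONE occurrence of ``term`` in ``text``.

    COMPLETE: the full normalized term occurs at token boundaries.
    PARTIAL: a proper contiguous subsequence of the term's tokens, of length
    >= ceil(n/2) and containing a non-stopword, occurs at token boundaries.
    Longer subsequences are preferred; ties go left-to-right.
    """
    if not term or not term.strip():
        raise ValueError("term must be non-empty")
    term_tokens = _norm_tokens(term)
    text_tokens = _norm_tokens(text)
    if not term_tokens:
        return MatchResult(NONE)
    if _find_token_subsequence(text_tokens, term_tokens) != -1:
        return MatchResult(COMPLETE, tuple(term_tokens))
    n = len(term_tokens)
    min_len = -(-n // 2)  # ceil(n/2)
    for length in range(n - 1, min_len - 1, -1):
        for start in range(0, n - length + 1):
            sub = term_tokens[start : start + length]
            if all(tok in stopwords for tok in sub):
                continue
            if _find_token_subsequence(text_tokens, sub) != -1:
                return MatchResult(PARTIAL, tuple(sub))
    return MatchResult(NONE)


def find_occurrences(doc: ClinicalDocument, surface: str) -> list[tuple[int, int]]:
    """All token-boundary occurrences of ``surface`` in the document.

    Occurrences are located on the normalized document, left-to-right
    greedy and non-overlapping, then mapped back to raw character spans.
    """
    if not surface or not surface.strip():
        raise ValueError("surface must be non-empty")
    norm_doc, offmap = normalize(doc.text)
    norm_surf = " ".join(_norm_tokens(surface))
    if not norm_surf or not norm_doc:
        return []
    spans: list[tuple[int, int]] = []
    pos = 0
    m = len(norm_surf)
    while True:
        idx = norm_doc.find(norm_surf, pos)
        if idx == -1:
            break
        at_start = idx == 0 or norm_doc[idx - 1] == " "
        at_end = idx + m == len(norm_doc) or norm_doc[idx + m] == " "
        if at_start and at_end:
            raw_start = offmap[idx][0]
            raw_end = offmap[idx + m - 1][1]
            spans.append((raw_start, raw_end))
            pos = idx + m
        else:
            pos = idx + 1
    return spans


def _resolve_claimed_spans(
    claims: list[tuple[int, int, str]],
) -> list[tuple[int, int, str]]:
    """Greedy longest-first selection of non-overlapping claimed spans.

    Ties break on smaller start, then category priority (DISEASE < SYMPTOM
    < PROCEDURE), so tagging is deterministic.
    """
    order = sorted(
        set(claims),
        key=lambda c: (-(c[1] - c[0]), c[0], CATEGORY_PRIORITY.get(c[2], 99)),
    )
    kept: list[tuple[int, int, str]] = []
    for s, e, cat in order:
        if all(e <= ks or ke <= s for ks, ke, _ in kept):
            kept.append((s, e, cat))
    return sorted(kept)


def strategy1_tag(
    doc: ClinicalDocument,
    silver_mentions: Sequence[EntityMention],
    output_raw: str,
    stopwords: frozenset[str] = STOPWORDS,
) -> IOBSequence:
    """Evaluation strategy 1: category-free tagging from free-form output.

    Iterates over the distinct silver surface forms of the document; for
    each one found (completely or partially) in the model output, every
    occurrence of the matched surface in the document is tagged B/I without
    category.  Works for any prompt variation since it ignores structure.
    """
    seen: set[str] = set()
    claims: list[tuple[int, int, str]] = []
    for mention in silver_mentions:
        surf_key = " ".join(_norm_tokens(mention.surface))
        if not surf_key or surf_key in seen:
            continue
        seen.add(surf_key)
        result = match_term_in_text(mention.surface, output_raw, stopwords)
        if result.kind == NONE:
            continue
        for s, e in find_occurrences(doc, result.matched_surface):
            claims.append((s, e, mention.category))
    resolved = _resolve_claimed_spans(claims)
    mentions = [
        EntityMention(doc.doc_id, s, e, doc.text[s:e], cat)
        for s, e, cat in resolved
    ]
    return to_iob(doc, mentions, categorical=False)


def strategy2_tag(
    doc: ClinicalDocument,
    parsed,
    stopwords: frozenset[str] = STOPWORDS,
) -> IOBSequence:
    """Evaluation strategy 2: categorical tagging from parsed entities.

    For each category and each parsed entity string, if the entity occurs
    (completely or partially) in the document, all occurrences of the
    matched surface are tagged with that category's B/I tags.  Entities
    with no document occurrence (hallucinations) contribute nothing.
    """
    claims: list[tuple[int, int, str]] = []
    for cat, entities in parsed.entities.items():
        for entity in entities:
            if not entity.strip():
                continue
            result = match_term_in_text(entity, doc.text, stopwords)
            if result.kind == NONE:
                continue
            for s, e in find_occurrences(doc, result.matched_surface):
                claims.append((s, e, cat))
    resolved = _resolve_claimed_spans(claims)
    mentions = [
        EntityMention(doc.doc_id, s, e, doc.text[s:e], cat)
        for s, e, cat in resolved
    ]
    return to_iob(doc, mentions, categorical=True)
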