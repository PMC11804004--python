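"""Unified multiclass silver-standard corpus construction.

Clinical case documents are distributed as one UTF-8 ``.txt`` file per
document, and each entity category (diseases, symptoms, medical procedures)
ships as a separate standoff annotation table.  This module merges the three
single-category annotation sets over their common documents, removes
cross-category span overlaps by keeping the longest span of each overlapping
cluster, assigns a train/test split from an explicit document-id list, and
converts the result to token-level IOB label sequences.

Offsets are 0-based, half-open ``[start, end)`` character indices on the raw
decoded text, the usual standoff-annotation convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("DISEASE", "SYMPTOM", "PROCEDURE")
#: tie-break priority when overlapping spans have equal length and start
CATEGORY_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}
SOURCES = ("DISTEMIST", "SYMPTEMIST", "MEDPROCNER", "SYNTHETIC")

TRAIN, TEST = "TRAIN", "TEST"


class CorpusError(ValueError):
    """Fatal error while building a corpus (bad inputs, id collisions)."""


@dataclass(frozen=True)
class ClinicalDocument:
    """One clinical case: an opaque id and its raw character-indexed text."""

    doc_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("doc_id must be non-empty")
        if not self.text:
            raise CorpusError(f"document {self.doc_id!r} has empty text")


@dataclass(frozen=True, order=True)
class EntityMention:
    """A category-labeled character span in one document.

    ``surface`` is the annotated string as distributed; it is trusted to
    equal ``text[start:end]`` up to whitespace normalization but offsets are
    authoritative (silver-standard surfaces are known to be noisy).
    """

    doc_id: str
    start: int
    end: int
    surface: str
    category: str
    source: str = "SYNTHETIC"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"invalid span ({self.start}, {self.end}) in {self.doc_id!r}"
            )
        if self.category not in CATEGORIES:
            raise CorpusError(f"unknown category {self.category!r}")
        if self.source not in SOURCES:
            raise CorpusError(f"unknown source {self.source!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class MergedCorpus:
    """Documents plus non-overlapping multiclass mentions and a split map."""

    documents: dict[str, ClinicalDocument]
    mentions: list[EntityMention]
    split: dict[str, str]

    def mentions_for(self, doc_id: str) -> list[EntityMention]:
        return sorted(m for m in self.mentions if m.doc_id == doc_id)

    def validate(self) -> None:
        if set(self.split) != set(self.documents):
            raise CorpusError("split map does not cover exactly the documents")
        by_doc: dict[str, list[EntityMention]] = {}
        for m in self.mentions:
            if m.doc_id not in self.documents:
                raise CorpusError(f"mention references unknown doc {m.doc_id!r}")
            if m.end > len(self.documents[m.doc_id].text):
                raise CorpusError(f"mention out of bounds in {m.doc_id!r}")
            by_doc.setdefault(m.doc_id, []).append(m)
        for doc_id, ms in by_doc.items():
            ms = sorted(ms)
            for a, b in zip(ms, ms[1:]):
                if a.overlaps(b):
                    raise CorpusError(f"overlapping mentions remain in {doc_id!r}")


@dataclass
class IOBSequence:
    """Token-per-position IOB labels for one document.

    ``tokens`` is an ordered list of ``(surface, start, end)`` with strictly
    increasing, non-overlapping half-open character spans; ``labels`` holds
    one tag per token drawn from ``O`` and ``B``/``I`` (optionally suffixed
    ``-CATEGORY``).
    """

    doc_id: str
    tokens: list[tuple[str, int, int]]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise CorpusError("tokens and labels length mismatch")

    def validate(self) -> None:
        prev_end = -1
        for _, s, e in self.tokens:
            if not (prev_end <= s < e):
                raise CorpusError("token spans not strictly increasing")
            prev_end = e
        prev = "O"
        for lab in self.labels:
            if lab != "O" and lab[0] not in "BI":
                raise CorpusError(f"bad label {lab!r}")
            if lab.startswith("I"):
                if prev == "O" or _label_cat(prev) != _label_cat(lab):
                    raise CorpusError("I tag without matching B/I predecessor")
            prev = lab


def _label_cat(label: str) -> str | None:
    return label[2:] if len(label) > 1 else None


@dataclass
class RowIssue:
    """A skipped or suspicious standoff row, kept for reporting."""

    path: str
    lineno: int
    message: str


# ---------------------------------------------------------------------------
# standoff / document IO


def read_standoff_tsv(
    path: str | Path,
    category: str,
    source: str,
    issues: list[RowIssue] | None = None,
) -> list[EntityMention]:
    """Read one per-category standoff annotation TSV.

    Expected columns (header row, tab-delimited): filename, label, start_span,
    end_span, text.  Malformed rows (non-integer offsets, ``end <= start``,
    too few fields) are skipped and recorded in ``issues``; an unreadable
    file raises :class:`CorpusError`.
    """
    path = Path(path)
    if issues is None:
        issues = []
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise CorpusError(f"cannot read standoff file {path}: {exc}") from exc
    mentions: list[EntityMention] = []
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 or not line.strip():
            continue  # header
        fields = line.split("\t")
        if len(fields) < 5:
            issues.append(RowIssue(str(path), lineno, "fewer than 5 fields"))
            continue
        doc_id, _label, start_s, end_s, surface = fields[:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            issues.append(RowIssue(str(path), lineno, "non-integer offsets"))
            continue
        if end <= start or start < 0:
            issues.append(RowIssue(str(path), lineno, f"bad span ({start}, {end})"))
            continue
        mentions.append(
            EntityMention(doc_id, start, end, surface, category, source)
        )
    for issue in issues:
        logger.warning("%s:%d: %s", issue.path, issue.lineno, issue.message)
    return mentions


def read_documents(directory: str | Path) -> list[ClinicalDocument]:
    """Read one UTF-8 ``.txt`` file per document; the file stem is the id."""
    directory = Path(directory)
    docs: dict[str, ClinicalDocument] = {}
    for path in sorted(directory.glob("*.txt")):
        doc_id = path.stem
        if doc_id in docs:
            raise CorpusError(f"duplicate doc_id {doc_id!r} in {directory}")
        try:
            text = path.read_text(encoding="utf-8")
        except UnicodeDecodeError as exc:
            raise CorpusError(f"undecodable file {path}: {exc}") from exc
        docs[doc_id] = ClinicalDocument(doc_id, text)
    return list(docs.values())


def intersect_common_documents(id_sets: Sequence[set[str]]) -> set[str]:
    """Document ids present in every source corpus."""
    if not id_sets:
        raise CorpusError("need at least one id set")
    common = set(id_sets[0])
    for s in id_sets[1:]:
        common &= s
    return common


# ---------------------------------------------------------------------------
# overlap resolution


def resolve_overlaps(mentions: Sequence[EntityMention]) -> list[EntityMention]:
    """Keep only the longest span of each overlapping cluster.

    Clusters are the transitive closure of pairwise character-span overlap.
    From each cluster exactly one mention survives: maximal ``end - start``,
    ties broken by smaller ``start`` then by category priority
    DISEASE < SYMPTOM < PROCEDURE.  Mentions that overlap nothing pass
    through unchanged.  Output is sorted by ``(start, end)``.
    """
    if not mentions:
        return []
    doc_ids = {m.doc_id for m in mentions}
    if len(doc_ids) != 1:
        raise CorpusError("resolve_overlaps expects mentions of one document")
    ordered = sorted(mentions, key=lambda m: (m.start, m.end))
    kept: list[EntityMention] = []
    # sweep: overlapping spans form a chain under transitive closure, so a
    # cluster is a maximal run where each mention overlaps the running
    # right frontier
    cluster: list[EntityMention] = []
    frontier = -1
    for m in ordered:
        if cluster and m.start >= frontier:
            kept.append(_cluster_winner(cluster))
            cluster = []
        cluster.append(m)
        frontier = max(frontier, m.end)
    if cluster:
        kept.append(_cluster_winner(cluster))
    return sorted(kept, key=lambda m: (m.start, m.end))


def _cluster_winner(cluster: list[EntityMention]) -> EntityMention:
    return min(
        cluster,
        key=lambda m: (-m.length, m.start, CATEGORY_PRIORITY[m.category]),
    )


def build_merged_corpus(
    documents: Iterable[ClinicalDocument],
    mention_lists: Sequence[Sequence[EntityMention]],
    test_ids: set[str],
) -> MergedCorpus:
    """Merge per-source mentions over the common documents and split them.

    ``documents`` is the common-document set (callers holding per-release
    document lists compute it with :func:`intersect_common_documents`; a
    document may legitimately lack annotations in some category).  Mentions
    outside the common set are dropped; the rest are pooled across sources
    and passed through :func:`resolve_overlaps` per document.
    """
    docs = {d.doc_id: d for d in list(documents)}
    missing = test_ids - set(docs)
    if missing:
        raise CorpusError(
            "test ids absent from common documents: " + ", ".join(sorted(missing))
        )
    per_doc: dict[str, list[EntityMention]] = {k: [] for k in docs}
    for lst in mention_lists:
        for m in lst:
            if m.doc_id in per_doc:
                if m.end > len(docs[m.doc_id].text):
                    logger.warning(
                        "mention (%d, %d) out of bounds in %s; dropped",
                        m.start, m.end, m.doc_id,
                    )
                    continue
                per_doc[m.doc_id].append(m)
    merged: list[EntityMention] = []
    for doc_id in sorted(per_doc):
        merged.extend(resolve_overlaps(per_doc[doc_id]))
    split = {k: (TEST if k in test_ids else TRAIN) for k in docs}
    corpus = MergedCorpus(documents=docs, mentions=merged, split=split)
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# tokenization and IOB conversion

_PUNCT = set(".,;:!?()[]{}\"'`“”‘’«»")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Offset-preserving whitespace tokenizer.

    Splits on whitespace, then separates leading/trailing punctuation into
    single-character tokens so that mention boundaries of the form
    ``fever,`` stay token-aligned.
    """
    tokens: list[tuple[str, int, int]] = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace():
            j += 1
        # peel leading punctuation
        k = i
        while k < j and text[k] in _PUNCT:
            tokens.append((text[k], k, k + 1))
            k += 1
        # locate trailing punctuation
        t = j
        while t > k and text[t - 1] in _PUNCT:
            t -= 1
        if k < t:
            tokens.append((text[k:t], k, t))
        for p in range(t, j):
            tokens.append((text[p], p, p + 1))
        i = j
    return tokens


def to_iob(
    doc: ClinicalDocument,
    mentions: Sequence[EntityMention],
    categorical: bool = True,
) -> IOBSequence:
    """Project non-overlapping mentions onto token-level IOB labels.

    A token belongs to a mention iff its span midpoint falls inside the
    mention; this resolves silver offsets that cut tokens. Tokens fully
    inside a mention always satisfy the midpoint rule, so token-aligned
    mentions round-trip exactly through :func:`decode_iob`.
    """
    tokens = tokenize(doc.text)
    ordered = sorted(mentions, key=lambda m: (m.start, m.end))
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise CorpusError("to_iob requires non-overlapping mentions")
    labels = ["O"] * len(tokens)
    mi = 0
    current: EntityMention | None = None
    for ti, (surface, s, e) in enumerate(tokens):
        mid = (s + e) / 2.0
        while mi < len(ordered) and ordered[mi].end <= mid:
            mi += 1
        if mi < len(ordered) and ordered[mi].start <= mid < ordered[mi].end:
            m = ordered[mi]
            if not (m.start <= s and e <= m.end):
                logger.warning(
                    "token %r (%d, %d) partially covered by mention (%d, %d) in %s",
                    surface, s, e, m.start, m.end, doc.doc_id,
                )
            tag = "B" if current is not m else "I"
            if categorical:
                tag = f"{tag}-{m.category}"
            labels[ti] = tag
            current = m
        else:
            current = None
    seq = IOBSequence(doc.doc_id, tokens, labels)
    seq.validate()
    return seq


def decode_iob(seq: IOBSequence) -> list[tuple[int, int, str | None]]:
    """Recover ``(start, end, category)`` spans from an IOB sequence."""
    spans: list[tuple[int, int, str | None]] = []
    start = end = None
    cat: str | None = None
    for (tok, s, e), lab in zip(seq.tokens, seq.labels):
        if lab.startswith("B"):
            if start is not None:
                spans.append((start, end, cat))
            start, end, cat = s, e, _label_cat(lab)
        elif lab.startswith("I"):
            end = e
        else:
            if start is not None:
                spans.append((start, end, cat))
            start = end = cat = None
    if start is not None:
        spans.append((start, end, cat))
    return spans


# ---------------------------------------------------------------------------
# statistics


def corpus_stats(corpus: MergedCorpus) -> pd.DataFrame:
    """Mention counts per (source, split) with totals, plus document stats.

    Returns a tidy DataFrame with one row per (source, split) combination,
    a ``TOTAL`` split row per source, and document-count / mean word length
    columns repeated on a ``__DOCS__`` summary block.
    """
    rows = []
    splits = (TRAIN, TEST)
    for source in SOURCES:
        counts = {
            sp: sum(
                1
                for m in corpus.mentions
                if m.source == source and corpus.split.get(m.doc_id) == sp
            )
            for sp in splits
        }
        if sum(counts.values()) == 0 and source == "SYNTHETIC":
            continue
        for sp in splits:
            rows.append({"source": source, "split": sp, "mentions": counts[sp]})
        rows.append(
            {"source": source, "split": "TOTAL", "mentions": sum(counts.values())}
        )
    df = pd.DataFrame(rows, columns=["source", "split", "mentions"])
    n_docs = {sp: sum(1 for v in corpus.split.values() if v == sp) for sp in splits}
    word_lengths = [len(d.text.split()) for d in corpus.documents.values()]
    meta = pd.DataFrame(
        [
            {
                "source": "__DOCS__",
                "split": sp,
                "mentions": sum(
                    1 for m in corpus.mentions if corpus.split.get(m.doc_id) == sp
                ),
                "n_docs": n_docs[sp],
            }
            for sp in splits
        ]
    )
    meta["mean_words"] = (
        sum(word_lengths) / len(word_lengths) if word_lengths else 0.0
    )
    return pd.concat([df, meta], ignore_index=True)


# ---------------------------------------------------------------------------
# serialization


def write_conll(
    sequences: Iterable[IOBSequence], path: str | Path
) -> None:
    """CoNLL-style token TAB tag lines, one blank-line-separated block per doc."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq in sequences:
            for (tok, _s, _e), lab in zip(seq.tokens, seq.labels):
                fh.write(f"{tok}\t{lab}\n")
            fh.write("\n")


def write_mentions_jsonl(mentions: Iterable[EntityMention], path: str | Path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                json.dumps(
                    {
                        "doc_id": m.doc_id,
                        "start": m.start,
                        "end": m.end,
                        "surface": m.surface,
                        "category": m.category,
                        "source": m.source,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
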