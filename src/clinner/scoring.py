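"""Precision/recall/F1 over IOB label sequences, and the valid-output ratio.

Two scoring granularities are provided because report readers legitimately
want both: ENTITY mode decodes mention spans and requires exact span+label
equality (strict entity-level matching); TOKEN mode compares non-O labels
positionally.  Scores are pooled over documents (micro), never averaged per
document, matching the "micro avg" convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import IOBSequence, decode_iob
from .parsing import ParsedEntitySet, parsed_ok

ENTITY, TOKEN = "ENTITY", "TOKEN"

#: pooled pseudo-label for micro aggregation
MICRO = "micro avg"


@dataclass
class LabelCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __iadd__(self, other: "LabelCounts") -> "LabelCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def support(self) -> int:
        return self.tp + self.fn


class ScoringError(ValueError):
    """Pred and gold sequences disagree on the underlying tokens."""


def score_iob(
    pred: IOBSequence, gold: IOBSequence, mode: str = ENTITY
) -> dict[str, LabelCounts]:
    """Per-label TP/FP/FN counts for one document.

    The label key is the category for categorical tags and ``"ENT"`` for
    binary B/I tags; a pooled entry is obtainable by summing.
    """
    if [t[1:] for t in pred.tokens] != [t[1:] for t in gold.tokens]:
        raise ScoringError(
            f"token sequences differ for {pred.doc_id!r}; pipeline bug"
        )
    counts: dict[str, LabelCounts] = {}
    if mode == ENTITY:
        pred_spans = Counter(
            (s, e, cat or "ENT") for s, e, cat in decode_iob(pred)
        )
        gold_spans = Counter(
            (s, e, cat or "ENT") for s, e, cat in decode_iob(gold)
        )
        for span, k in pred_spans.items():
            label = span[2]
            c = counts.setdefault(label, LabelCounts())
            matched = min(k, gold_spans.get(span, 0))
            c.tp += matched
            c.fp += k - matched
        for span, k in gold_spans.items():
            label = span[2]
            c = counts.setdefault(label, LabelCounts())
            c.fn += k - min(k, pred_spans.get(span, 0))
    elif mode == TOKEN:
        for plab, glab in zip(pred.labels, gold.labels):
            pcat = _token_label(plab)
            gcat = _token_label(glab)
            if pcat is not None and pcat == gcat:
                counts.setdefault(pcat, LabelCounts()).tp += 1
            else:
                if pcat is not None:
                    counts.setdefault(pcat, LabelCounts()).fp += 1
                if gcat is not None:
                    counts.setdefault(gcat, LabelCounts()).fn += 1
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")
    return counts


def _token_label(label: str) -> str | None:
    if label == "O":
        return None
    return label[2:] if len(label) > 1 else "ENT"


def merge_counts(
    count_maps: Iterable[Mapping[str, LabelCounts]],
) -> dict[str, LabelCounts]:
    """Pool per-document count maps (micro pooling)."""
    pooled: dict[str, LabelCounts] = {}
    for cmap in count_maps:
        for label, c in cmap.items():
            pooled.setdefault(label, LabelCounts()).__iadd__(c)
    return pooled


def aggregate(
    count_maps: Iterable[Mapping[str, LabelCounts]],
) -> pd.DataFrame:
    """Per-label and micro-averaged P/R/F1 rows from pooled counts.

    Division by zero yields 0.0; the ``support`` column lets readers spot
    empty labels.  The micro row pools counts across labels before dividing.
    """
    pooled = merge_counts(count_maps)
    micro = LabelCounts()
    rows = []
    for label in sorted(pooled):
        c = pooled[label]
        micro += c
        rows.append(_row(label, c))
    rows.append(_row(MICRO, micro))
    return pd.DataFrame(
        rows, columns=["label", "precision", "recall", "f1", "support", "tp", "fp", "fn"]
    )


def _row(label: str, c: LabelCounts) -> dict:
    return {
        "label": label,
        "precision": c.precision,
        "recall": c.recall,
        "f1": c.f1,
        "support": c.support,
        "tp": c.tp,
        "fp": c.fp,
        "fn": c.fn,
    }


def valid_output_ratio(parsed_sets: Sequence[ParsedEntitySet]) -> float:
    """Fraction of documents whose generation parsed into >= 1 entity."""
    if not parsed_sets:
        raise ValueError("valid_output_ratio needs at least one document")
    return sum(1 for p in parsed_sets if parsed_ok(p)) / len(parsed_sets)


# ---------------------------------------------------------------------------
# report assembly


def build_strategy1_report(
    results: Mapping[tuple[str, int], Iterable[Mapping[str, LabelCounts]]],
) -> pd.DataFrame:
    """P/R/F1 per (model, variation) for the category-free strategy."""
    rows = []
    for (model_id, variation), count_maps in sorted(results.items()):
        pooled = merge_counts(count_maps)
        total = LabelCounts()
        for c in pooled.values():
            total += c
        rows.append(
            {"model": model_id, "variation": variation, **_row("ENT", total)}
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "model", "variation", "label", "precision", "recall", "f1",
            "support", "tp", "fp", "fn",
        ],
    )
    return df.drop(columns=["label"])


def build_strategy2_report(
    results: Mapping[tuple[str, int], Iterable[Mapping[str, LabelCounts]]],
) -> pd.DataFrame:
    """P/R/F1 per (model, variation, category) plus a micro-avg row each."""
    frames = []
    for (model_id, variation), count_maps in sorted(results.items()):
        table = aggregate(count_maps)
        table.insert(0, "variation", variation)
        table.insert(0, "model", model_id)
        frames.append(table)
    if not frames:
        return pd.DataFrame(
            columns=[
                "model", "variation", "label", "precision", "recall", "f1",
                "support", "tp", "fp", "fn",
            ]
        )
    return pd.concat(frames, ignore_index=True).rename(
        columns={"label": "category"}
    )


def build_validity_report(
    parsed_by_run: Mapping[tuple[str, int], Sequence[ParsedEntitySet]],
) -> pd.DataFrame:
    """Valid-output ratio per (model, variation)."""
    rows = [
        {
            "model": model_id,
            "variation": variation,
            "ratio": valid_output_ratio(list(sets)),
            "n_docs": len(list(sets)),
        }
        for (model_id, variation), sets in sorted(parsed_by_run.items())
    ]
    return pd.DataFrame(rows, columns=["model", "variation", "ratio", "n_docs"])
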