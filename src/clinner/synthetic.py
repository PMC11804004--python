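"""Synthetic clinical-style corpora and a parameterized LLM-output simulator.

The generator plants known entity mentions of the three categories into
filler text so that every pipeline stage — merging, overlap resolution, IOB
conversion, parsing, alignment, scoring — runs offline with exact ground
truth.  Category vocabularies, the filler word list and the hallucination
vocabulary are pairwise disjoint, so closed-form predictions hold: a planted
mention occurs exactly where the bookkeeping says and nowhere else, and a
hallucinated surface never occurs in any document.

The simulator emulates the observed failure modes of real generations:
missed entities (``recall_true``), invented entities (``halluc_rate``),
wrong categories (``miscat_rate``), malformed envelopes (``corrupt_rate``:
unquoted keys, dropped categories, unclosed brackets, prose refusals) and
truncation (``truncate_rate``).  Each document's corruption draws come from
a dedicated stream, so runs with the same seed are coupled across corruption
rates: raising ``corrupt_rate`` only ever corrupts a superset of documents.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field

from .corpus import (
    CATEGORIES,
    ClinicalDocument,
    EntityMention,
    MergedCorpus,
    resolve_overlaps,
    TRAIN,
    TEST,
)
from .llm import LLMOutput
from .parsing import ParsedEntitySet, to_keyed_list

_SOURCE_FOR = {
    "DISEASE": "DISTEMIST",
    "SYMPTOM": "SYMPTEMIST",
    "PROCEDURE": "MEDPROCNER",
}

DISEASE_VOCAB = (
    "nephropathy cirrhosis lymphoma sarcoidosis tuberculosis meningitis "
    "pancreatitis endocarditis osteomyelitis psoriasis hepatitis anemia "
    "leukemia melanoma asthma diverticulitis pyelonephritis cholecystitis "
    "appendicitis bronchiectasis amyloidosis vasculitis myelofibrosis "
    "glomerulonephritis thalassemia pericarditis sinusitis pneumonia "
    "emphysema gastritis"
).split()

SYMPTOM_VOCAB = (
    "fever dysuria fatigue nausea vomiting sweating pruritus dyspnea "
    "headache dizziness palpitations anorexia malaise chills cough wheezing "
    "hematuria jaundice myalgia arthralgia syncope tinnitus paresthesia "
    "insomnia diarrhea constipation epistaxis hoarseness photophobia polyuria"
).split()

PROCEDURE_VOCAB = (
    "ultrasound biopsy colonoscopy radiograph angiography endoscopy "
    "thoracentesis laparotomy nephrectomy splenectomy appendectomy "
    "cystoscopy bronchoscopy echocardiogram electrocardiogram tomography "
    "scintigraphy dialysis paracentesis tracheostomy gastroscopy mammography "
    "arthroscopy craniotomy phlebotomy intubation catheterization lumpectomy "
    "thyroidectomy venography"
).split()

DEFAULT_VOCAB = {
    "DISEASE": DISEASE_VOCAB,
    "SYMPTOM": SYMPTOM_VOCAB,
    "PROCEDURE": PROCEDURE_VOCAB,
}

#: neutral filler, disjoint from every category and hallucination vocabulary
FILLER_WORDS = (
    "patient hospital admitted history clinical examination reported "
    "presented routine visit months weeks days stable normal findings "
    "review records noted during after before initial general condition "
    "observed discharged treatment management evaluation status baseline "
    "results values levels laboratory ward service consult referred course "
    "without further remained daily morning evening later today department "
    "center team staff plan notes summary section"
).split()

#: invented drug-like surfaces guaranteed absent from generated documents
HALLUCINATION_VOCAB = (
    "xylofarin quorbital zentrazol mivaxone drelbamide plenorix vantrosine "
    "kelbizumab orfanitide juvelamine seprotide waldrenine"
).split()


@dataclass
class SyntheticSpec:
    """Shape parameters for a generated corpus.

    Defaults emulate the real silver-standard corpus shape: multi-paragraph
    clinical-style documents averaging 333 words with mentions of all three
    categories.
    """

    n_docs: int = 50
    words_per_doc: int = 333
    mentions_per_doc: float = 3.0  # mean per category
    overlap_rate: float = 0.0
    repeat_rate: float = 0.0
    test_fraction: float = 0.1
    vocab: dict[str, list[str]] = field(
        default_factory=lambda: {c: list(DEFAULT_VOCAB[c]) for c in CATEGORIES}
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("overlap_rate", "repeat_rate", "test_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_docs < 0 or self.words_per_doc <= 0 or self.mentions_per_doc < 0:
            raise ValueError("counts must be positive")
        for cat in CATEGORIES:
            if not self.vocab.get(cat):
                raise ValueError(f"empty vocabulary for category {cat}")


@dataclass
class SimulatorParams:
    """Error-mode parameters of the LLM-output simulator."""

    recall_true: float = 1.0
    halluc_rate: float = 0.0
    miscat_rate: float = 0.0
    corrupt_rate: float = 0.0
    truncate_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("recall_true", "miscat_rate", "corrupt_rate", "truncate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.halluc_rate < 0:
            raise ValueError("halluc_rate must be >= 0")


@dataclass
class GoldBook:
    """Generator bookkeeping: what was planted, what should survive merging."""

    planted: list[EntityMention] = field(default_factory=list)
    surviving: list[EntityMention] = field(default_factory=list)

    def planted_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for m in self.planted:
            out[m.category] += 1
        return out

    def surviving_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for m in self.surviving:
            out[m.category] += 1
        return out


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    # Knuth's method; lambdas here are small
    limit = pow(2.718281828459045, -lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def generate_corpus(spec: SyntheticSpec) -> tuple[MergedCorpus, GoldBook]:
    """Generate a corpus of filler documents with planted mentions.

    With ``overlap_rate`` > 0, a planted mention may receive a longer
    cross-category twin covering it plus the following filler word, so that
    overlap resolution has real work to do; the bookkeeping records both the
    planted mentions and the set expected to survive resolution.
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = random.Random(f"synthetic-corpus:{spec.seed}")
    documents: dict[str, ClinicalDocument] = {}
    book = GoldBook()
    n_test = int(round(spec.n_docs * spec.test_fraction))
    split: dict[str, str] = {}
    for i in range(spec.n_docs):
        doc_id = f"syn{i:04d}"
        doc, planted, surviving = _generate_document(doc_id, spec, rng)
        documents[doc_id] = doc
        book.planted.extend(planted)
        book.surviving.extend(surviving)
        split[doc_id] = TEST if i < n_test else TRAIN
    mentions: list[EntityMention] = []
    for doc_id in sorted(documents):
        mentions.extend(
            resolve_overlaps([m for m in book.planted if m.doc_id == doc_id])
        )
    corpus = MergedCorpus(documents=documents, mentions=mentions, split=split)
    corpus.validate()
    return corpus, book


def _generate_document(
    doc_id: str, spec: SyntheticSpec, rng: random.Random
) -> tuple[ClinicalDocument, list[EntityMention], list[EntityMention]]:
    n_words = max(30, int(round(rng.gauss(spec.words_per_doc, spec.words_per_doc * 0.1))))
    words = [rng.choice(FILLER_WORDS) for _ in range(n_words)]
    occupied: set[int] = set()

    # choose term slots: (slot, term, category, twin_category or None, repeat_slot)
    plans: list[tuple[int, str, str, str | None]] = []
    for cat in CATEGORIES:
        pool = list(spec.vocab[cat])
        rng.shuffle(pool)
        k = min(_poisson(rng, spec.mentions_per_doc), len(pool), n_words // 6)
        for term in pool[:k]:
            slot = _free_slot(rng, n_words, occupied, margin=1)
            if slot is None:
                continue
            occupied.update({slot, slot + 1})  # reserve follower for twins
            twin_cat = None
            if rng.random() < spec.overlap_rate:
                twin_cat = rng.choice([c for c in CATEGORIES if c != cat])
            plans.append((slot, term, cat, twin_cat))
            if rng.random() < spec.repeat_rate:
                rslot = _free_slot(rng, n_words, occupied, margin=1)
                if rslot is not None:
                    occupied.update({rslot, rslot + 1})
                    plans.append((rslot, term, cat, None))

    for slot, term, _cat, _twin in plans:
        words[slot] = term

    text = " ".join(words)
    starts = []
    pos = 0
    for w in words:
        starts.append(pos)
        pos += len(w) + 1
    doc = ClinicalDocument(doc_id, text)

    planted: list[EntityMention] = []
    surviving: list[EntityMention] = []
    for slot, term, cat, twin_cat in sorted(plans):
        s, e = starts[slot], starts[slot] + len(term)
        m = EntityMention(doc_id, s, e, term, cat, _SOURCE_FOR[cat])
        planted.append(m)
        if twin_cat is None:
            surviving.append(m)
        else:
            te = starts[slot + 1] + len(words[slot + 1])
            twin = EntityMention(
                doc_id, s, te, text[s:te], twin_cat, _SOURCE_FOR[twin_cat]
            )
            planted.append(twin)
            surviving.append(twin)  # longer span wins resolution
    return doc, planted, surviving


def _free_slot(
    rng: random.Random, n_words: int, occupied: set[int], margin: int
) -> int | None:
    candidates = [
        i
        for i in range(1, n_words - margin - 1)
        if all(j not in occupied for j in range(i - 1, i + margin + 1))
    ]
    if not candidates:
        return None
    return rng.choice(candidates)


# ---------------------------------------------------------------------------
# LLM-output simulation

_CAT_NAME = {"DISEASE": "disease", "SYMPTOM": "symptom", "PROCEDURE": "medical procedure"}
_CAT_HEADER = {
    "DISEASE": "Diseases",
    "SYMPTOM": "Symptoms",
    "PROCEDURE": "Medical procedures",
}

_REFUSAL = (
    "I'm sorry, but I cannot help with labeling this clinical note as it "
    "appears to contain personal health information."
)


def simulate_llm_output(
    doc: ClinicalDocument,
    gold_mentions: list[EntityMention],
    params: SimulatorParams,
    variation: int,
    model_id: str = "simulated-llm",
) -> LLMOutput:
    """One simulated generation for a document.

    Each gold mention is emitted independently with probability
    ``recall_true`` (with a wrong category at rate ``miscat_rate``);
    ``Poisson(halluc_rate)`` hallucinated surfaces are appended; one envelope
    corruption is applied with probability ``corrupt_rate`` and truncation
    with probability ``truncate_rate``.  Deterministic given
    ``(params.seed, doc_id, variation)``; every error mode consumes draws
    from its own stream so rates can be varied independently under a fixed
    seed.
    """
    params.validate()
    if variation not in (1, 2, 3):
        raise ValueError(f"unknown prompt variation {variation}")
    base = f"sim:{params.seed}:{doc.doc_id}:{variation}"
    rng_emit = random.Random(base + ":emit")
    rng_halluc = random.Random(base + ":halluc")
    rng_corrupt = random.Random(base + ":corrupt")
    rng_trunc = random.Random(base + ":trunc")

    emitted: list[tuple[str, str]] = []  # (surface, category as emitted)
    for m in sorted(gold_mentions):
        u_emit, u_miscat, u_which = (
            rng_emit.random(), rng_emit.random(), rng_emit.random(),
        )
        if u_emit >= params.recall_true:
            continue
        cat = m.category
        if u_miscat < params.miscat_rate:
            others = [c for c in CATEGORIES if c != cat]
            cat = others[int(u_which * len(others)) % len(others)]
        emitted.append((m.surface, cat))

    n_halluc = _poisson(rng_halluc, params.halluc_rate)
    for _ in range(n_halluc):
        surface = rng_halluc.choice(HALLUCINATION_VOCAB)
        cat = rng_halluc.choice(CATEGORIES)
        emitted.append((surface, cat))

    raw = _render(emitted, variation)

    u_corrupt = rng_corrupt.random()
    mode = rng_corrupt.choice(_CORRUPTION_MODES[variation])
    if u_corrupt < params.corrupt_rate:
        raw = _corrupt(raw, emitted, variation, mode)

    u_trunc = rng_trunc.random()
    frac = rng_trunc.uniform(0.3, 0.9)
    meta: dict = {"simulated": True, "n_hallucinated": n_halluc}
    if u_trunc < params.truncate_rate:
        raw = raw[: int(len(raw) * frac)]
        meta["truncated"] = True

    return LLMOutput(doc.doc_id, model_id, variation, raw, meta)


def _entity_set(emitted: list[tuple[str, str]]) -> ParsedEntitySet:
    p = ParsedEntitySet(doc_id="", variation=0)
    for surface, cat in emitted:
        p.entities[cat].append(surface)
    return p


def _render(emitted: list[tuple[str, str]], variation: int) -> str:
    if variation == 1:
        lines = ["Here are the entities found in the clinical note:", ""]
        for idx, cat in enumerate(CATEGORIES, start=1):
            lines.append(f"{idx}. {_CAT_HEADER[cat]}:")
            lines.extend(
                f"- {surface}" for surface, c in emitted if c == cat
            )
            lines.append("")
        return "\n".join(lines)
    if variation == 2:
        return (
            "Here are the entities of types disease, symptom, and medical "
            "procedure identified in the clinical document:\n"
            + to_keyed_list(_entity_set(emitted))
        )
    annotations = [
        {"entity": surface, "category": _CAT_NAME[cat]} for surface, cat in emitted
    ]
    return "Here is the JSON output:\n" + json.dumps(
        {"annotations": annotations}, ensure_ascii=False
    )


_CORRUPTION_MODES = {
    1: ["prose_refusal"],
    2: ["prose_refusal", "keyword_mangle", "bullet_style"],
    3: ["prose_refusal", "missing_categories", "unquoted_keys", "unclosed_bracket"],
}


def _corrupt(
    raw: str, emitted: list[tuple[str, str]], variation: int, mode: str
) -> str:
    if mode == "prose_refusal":
        return _REFUSAL
    if mode == "keyword_mangle":
        return re.sub(
            r"(?i)diseases|symptoms|medical procedures", "entities", raw
        )
    if mode == "bullet_style":
        return _render(emitted, 1)
    if mode == "missing_categories":
        annotations = [{"entity": surface} for surface, _cat in emitted]
        return json.dumps({"annotations": annotations}, ensure_ascii=False)
    if mode == "unquoted_keys":
        items = ", ".join(
            "{entity: %s, category: %s}" % (surface, _CAT_NAME[cat])
            for surface, cat in emitted
        )
        return "{ annotations:[ " + items + " ] }"
    if mode == "unclosed_bracket":
        return raw.rstrip().rstrip("}").rstrip().rstrip("]")
    raise ValueError(f"unknown corruption mode {mode!r}")


def expected_metrics(
    spec: SyntheticSpec, params: SimulatorParams
) -> dict[str, dict[str, float]]:
    """Closed-form strategy-level predictions for unique-surface corpora.

    Valid only when the construction guarantees each planted surface occurs
    exactly once (``overlap_rate = repeat_rate = 0``) and no envelope faults
    interfere (``corrupt_rate = truncate_rate = 0``).  Hallucinations never
    occur in documents, so precision is unaffected by ``halluc_rate``:
    strategy 2 micro precision is ``1 - miscat_rate`` and recall
    ``recall_true * (1 - miscat_rate)``; the category-free strategy 1
    ignores category errors entirely.
    """
    spec.validate()
    params.validate()
    if spec.overlap_rate != 0 or spec.repeat_rate != 0:
        raise ValueError("closed form requires overlap_rate = repeat_rate = 0")
    if params.corrupt_rate != 0 or params.truncate_rate != 0:
        raise ValueError("closed form requires corrupt_rate = truncate_rate = 0")
    r, m = params.recall_true, params.miscat_rate
    return {
        "strategy1": {"precision": 1.0, "recall": r},
        "strategy2": {"precision": 1.0 - m, "recall": r * (1.0 - m)},
    }
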