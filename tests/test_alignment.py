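"""Term matching, occurrence finding, and the two tagging strategies."""

import math
import random

import pytest

from clinner.alignment import (
    COMPLETE,
    NONE,
    PARTIAL,
    find_occurrences,
    match_term_in_text,
    normalize,
    strategy1_tag,
    strategy2_tag,
)
from clinner.corpus import ClinicalDocument, EntityMention, decode_iob, tokenize
from clinner.parsing import ParsedEntitySet

CATS = ("DISEASE", "SYMPTOM", "PROCEDURE")


# -------------------------------------------------------------- normalize


def test_normalize_strips_punct_and_collapses_whitespace():
    norm, offmap = normalize("Fever,  chills")
    assert norm == "fever chills"
    # map round-trips: 'fever' occupies raw chars 0..5, 'chills' 8..14
    assert offmap[0] == (0, 1)
    assert offmap[len("fever ")][0] == 8  # first char of 'chills'
    assert offmap[-1] == (13, 14)


def test_normalize_identity_on_normal_text():
    norm, offmap = normalize("fever chills")
    assert norm == "fever chills"
    assert [m[0] for m in offmap[:5]] == [0, 1, 2, 3, 4]


def test_normalize_empty():
    assert normalize("") == ("", [])


# ------------------------------------------------------------- matching


def test_complete_match():
    assert match_term_in_text("renal ultrasound", "a renal ultrasound done").kind == COMPLETE


def test_partial_match_two_of_three_tokens():
    r = match_term_in_text("left lumbar pain", "presented with lumbar pain today")
    assert r.kind == PARTIAL
    assert r.matched_tokens == ("lumbar", "pain")
    assert math.ceil(3 / 2) == 2  # the rule threshold the match satisfies


def test_no_match():
    assert match_term_in_text("fever", "no complaints at all").kind == NONE


def test_single_token_term_cannot_match_partially():
    assert match_term_in_text("fever", "feverish but fine").kind == NONE


def test_stopword_only_subsequence_rejected():
    # 'of the' is a contiguous 2-token subsequence of the 4-token term but
    # contains no content word, so it cannot support a partial match
    r = match_term_in_text("tip of the tongue", "none of the above")
    assert r.kind == NONE


def test_match_is_case_and_punct_insensitive():
    assert match_term_in_text("Fever", "mild fever, improving").kind == COMPLETE


# ---------------------------------------------------------- occurrences


def test_find_occurrences_all_instances():
    doc = ClinicalDocument("d", "fever and chills and fever")
    assert find_occurrences(doc, "fever") == [(0, 5), (21, 26)]


def test_find_occurrences_absent():
    doc = ClinicalDocument("d", "fever and chills")
    assert find_occurrences(doc, "dysuria") == []


def test_find_occurrences_whole_document():
    doc = ClinicalDocument("d", "renal ultrasound")
    assert find_occurrences(doc, "renal ultrasound") == [(0, 16)]


def test_find_occurrences_token_boundary_only():
    doc = ClinicalDocument("d", "feverish fever")
    assert find_occurrences(doc, "fever") == [(9, 14)]


def test_find_occurrences_exhaustive_scan_oracle():
    rng = random.Random(4)
    pool = ["fever", "pain", "renal", "scan", "mild", "flank"]
    for _ in range(50):
        words = [rng.choice(pool) for _ in range(rng.randrange(1, 30))]
        doc = ClinicalDocument("d", " ".join(words))
        n_sub = rng.randrange(1, 3)
        i = rng.randrange(0, len(words) - n_sub + 1)
        surface = " ".join(words[i : i + n_sub])
        got = find_occurrences(doc, surface)
        # oracle: greedy scan over token windows
        expected, j = [], 0
        toks = tokenize(doc.text)
        while j <= len(toks) - n_sub:
            window = [t[0] for t in toks[j : j + n_sub]]
            if window == surface.split():
                expected.append((toks[j][1], toks[j + n_sub - 1][2]))
                j += n_sub
            else:
                j += 1
        assert got == expected


# ------------------------------------------------------------ strategy 1


def _silver(doc_id, spans_cats, text):
    return [
        EntityMention(doc_id, s, e, text[s:e], c) for s, e, c in spans_cats
    ]


def test_strategy1_no_shared_terms_gives_all_O():
    doc = ClinicalDocument("d", "fever and chills")
    silver = _silver("d", [(0, 5, "SYMPTOM")], doc.text)
    seq = strategy1_tag(doc, silver, "the model refused to answer")
    assert set(seq.labels) == {"O"}


def test_strategy1_self_consistency_perfect_recall():
    text = "cirrhosis treated after renal ultrasound and dysuria"
    doc = ClinicalDocument("d", text)
    silver = _silver(
        "d", [(0, 9, "DISEASE"), (24, 40, "PROCEDURE"), (45, 52, "SYMPTOM")], text
    )
    output = " ".join(m.surface for m in silver)
    seq = strategy1_tag(doc, silver, output)
    from clinner.corpus import to_iob

    gold = to_iob(doc, silver, categorical=False)
    assert seq.labels == gold.labels


def test_strategy1_tags_all_document_occurrences():
    text = "fever noted again fever persists"
    doc = ClinicalDocument("d", text)
    silver = _silver("d", [(0, 5, "SYMPTOM")], text)
    seq = strategy1_tag(doc, silver, "the patient reports fever")
    assert [(s, e) for s, e, _ in decode_iob(seq)] == [(0, 5), (18, 23)]


def test_strategy1_binary_tags_carry_no_category():
    doc = ClinicalDocument("d", "fever")
    silver = _silver("d", [(0, 5, "SYMPTOM")], doc.text)
    seq = strategy1_tag(doc, silver, "fever")
    assert seq.labels == ["B"]


# ------------------------------------------------------------ strategy 2


def _parsed(entities):
    p = ParsedEntitySet(doc_id="d", variation=2)
    for cat, items in entities.items():
        p.entities[cat] = list(items)
    return p


def test_strategy2_hallucination_changes_nothing():
    doc = ClinicalDocument("d", "fever and chills")
    baseline = strategy2_tag(doc, _parsed({"SYMPTOM": ["fever"]}))
    with_halluc = strategy2_tag(
        doc, _parsed({"SYMPTOM": ["fever"], "DISEASE": ["xylofarin"]})
    )
    assert baseline.labels == with_halluc.labels


def test_strategy2_categorical_tagging():
    doc = ClinicalDocument("d", "patient has fever today")
    seq = strategy2_tag(doc, _parsed({"SYMPTOM": ["fever"]}))
    assert seq.labels == ["O", "O", "B-SYMPTOM", "O"]


def test_strategy2_cross_category_conflict_resolved_deterministically():
    doc = ClinicalDocument("d", "fever noted")
    seq = strategy2_tag(
        doc, _parsed({"DISEASE": ["fever"], "SYMPTOM": ["fever"]})
    )
    seq.validate()
    assert seq.labels[0] == "B-DISEASE"  # category priority wins the tie


def test_strategy2_longest_claim_wins():
    doc = ClinicalDocument("d", "left lumbar pain persists")
    seq = strategy2_tag(
        doc, _parsed({"SYMPTOM": ["left lumbar pain"], "DISEASE": ["lumbar"]})
    )
    assert seq.labels == ["B-SYMPTOM", "I-SYMPTOM", "I-SYMPTOM", "O"]


def test_strategy2_monotone_in_grounded_entities():
    doc = ClinicalDocument("d", "fever and dysuria with cirrhosis")
    small = strategy2_tag(doc, _parsed({"SYMPTOM": ["fever"]}))
    large = strategy2_tag(
        doc, _parsed({"SYMPTOM": ["fever", "dysuria"], "DISEASE": ["cirrhosis"]})
    )
    tagged_small = {i for i, lab in enumerate(small.labels) if lab != "O"}
    tagged_large = {i for i, lab in enumerate(large.labels) if lab != "O"}
    assert tagged_small <= tagged_large


# ------------------------------------------- randomized validity + oracle


def _brute_force_strategy2(doc, parsed):
    """Independent tagger: enumerate every token window occurrence of every
    claimed surface, then apply the same longest-first resolution."""
    toks = tokenize(doc.text)
    claims = []
    priority = {c: i for i, c in enumerate(CATS)}
    for cat, entities in parsed.entities.items():
        for entity in entities:
            r = match_term_in_text(entity, doc.text)
            if r.kind == NONE:
                continue
            target = r.matched_tokens
            n = len(target)
            j = 0
            while j <= len(toks) - n:
                window = tuple(t[0].casefold() for t in toks[j : j + n])
                if window == target:
                    claims.append((toks[j][1], toks[j + n - 1][2], cat))
                    j += n
                else:
                    j += 1
    order = sorted(set(claims), key=lambda c: (-(c[1] - c[0]), c[0], priority[c[2]]))
    kept = []
    for s, e, cat in order:
        if all(e <= ks or ke <= s for ks, ke, _ in kept):
            kept.append((s, e, cat))
    labels = ["O"] * len(toks)
    for s, e, cat in kept:
        first = True
        for i, (_w, ts, te) in enumerate(toks):
            if ts >= s and te <= e:
                labels[i] = ("B-" if first else "I-") + cat
                first = False
    return labels


@pytest.mark.parametrize("seed", range(8))
def test_strategy2_matches_bruteforce_on_small_docs(seed):
    rng = random.Random(seed)
    pool = ["fever", "pain", "renal", "scan", "mild", "flank", "lumbar"]
    for _ in range(25):
        words = [rng.choice(pool) for _ in range(rng.randrange(3, 50))]
        doc = ClinicalDocument("d", " ".join(words))
        parsed = _parsed(
            {
                cat: [
                    " ".join(rng.choice(pool) for _ in range(rng.randrange(1, 3)))
                    for _ in range(rng.randrange(0, 3))
                ]
                for cat in CATS
            }
        )
        seq = strategy2_tag(doc, parsed)
        seq.validate()
        assert seq.labels == _brute_force_strategy2(doc, parsed)


@pytest.mark.parametrize("seed", range(4))
def test_both_strategies_emit_valid_iob_on_random_inputs(seed):
    rng = random.Random(100 + seed)
    pool = ["fever", "pain", "renal", "scan", "mild"]
    for _ in range(20):
        words = [rng.choice(pool) for _ in range(rng.randrange(2, 30))]
        text = " ".join(words)
        doc = ClinicalDocument("d", text)
        toks = tokenize(text)
        i = rng.randrange(0, len(toks))
        silver = [
            EntityMention("d", toks[i][1], toks[i][2], toks[i][0], rng.choice(CATS))
        ]
        raw = " ".join(rng.choice(pool) for _ in range(10))
        strategy1_tag(doc, silver, raw).validate()
        parsed = _parsed({rng.choice(CATS): [rng.choice(pool)]})
        strategy2_tag(doc, parsed).validate()
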