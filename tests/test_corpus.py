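"""Corpus construction: standoff IO, overlap resolution, IOB conversion."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinner.corpus import (
    CATEGORY_PRIORITY,
    ClinicalDocument,
    CorpusError,
    EntityMention,
    RowIssue,
    build_merged_corpus,
    corpus_stats,
    decode_iob,
    intersect_common_documents,
    read_documents,
    read_standoff_tsv,
    resolve_overlaps,
    to_iob,
    tokenize,
)
from conftest import random_mentions


# ---------------------------------------------------------------------- IO


def test_read_standoff_tsv_fixture(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        "filename\tlabel\tstart_span\tend_span\ttext\n"
        "d1\tSINTOMA\t0\t5\tfever\n"
        "d1\tSINTOMA\t10\t16\tnausea\n",
        encoding="utf-8",
    )
    mentions = read_standoff_tsv(path, "SYMPTOM", "SYMPTEMIST")
    assert [(m.start, m.end, m.surface) for m in mentions] == [
        (0, 5, "fever"),
        (10, 16, "nausea"),
    ]
    assert all(m.category == "SYMPTOM" and m.source == "SYMPTEMIST" for m in mentions)


def test_read_standoff_tsv_header_only(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text("filename\tlabel\tstart_span\tend_span\ttext\n")
    assert read_standoff_tsv(path, "DISEASE", "DISTEMIST") == []


def test_read_standoff_tsv_skips_malformed_rows(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        "filename\tlabel\tstart_span\tend_span\ttext\n"
        "d1\tX\t9\t4\tbackwards\n"  # end < start
        "d1\tX\tfoo\t4\tbad\n"  # non-integer
        "d1\tX\t0\t5\tfever\n",
        encoding="utf-8",
    )
    issues: list[RowIssue] = []
    mentions = read_standoff_tsv(path, "SYMPTOM", "SYMPTEMIST", issues)
    assert len(mentions) == 1 and mentions[0].surface == "fever"
    assert len(issues) == 2


def test_read_standoff_missing_file_is_fatal(tmp_path):
    with pytest.raises(CorpusError):
        read_standoff_tsv(tmp_path / "nope.tsv", "DISEASE", "DISTEMIST")


def test_read_documents(corpus_files):
    docs = read_documents(corpus_files["docs"])
    assert sorted(d.doc_id for d in docs) == ["d1", "d2", "d3"]
    assert all(d.text == corpus_files["texts"][d.doc_id] for d in docs)


def test_read_documents_empty_dir(tmp_path):
    assert read_documents(tmp_path) == []


def test_intersect_common_documents():
    assert intersect_common_documents([{"a", "b"}, {"b", "c"}]) == {"b"}
    assert intersect_common_documents([{"a"}, {"a"}]) == {"a"}
    assert intersect_common_documents([{"a"}, {"b"}]) == set()


# -------------------------------------------------------- overlap resolution


def _overlap_oracle(mentions):
    """Brute force: transitive-closure clusters, then argmax by (length,
    -start, category priority)."""
    ms = list(mentions)
    n = len(ms)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if ms[i].overlaps(ms[j]):
                parent[find(i)] = find(j)
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(ms[i])
    winners = [
        min(c, key=lambda m: (-m.length, m.start, CATEGORY_PRIORITY[m.category]))
        for c in clusters.values()
    ]
    return sorted(winners, key=lambda m: (m.start, m.end))


def test_resolve_overlaps_disjoint_identity():
    ms = [
        EntityMention("d", 10, 16, "nausea", "SYMPTOM"),
        EntityMention("d", 0, 5, "fever", "SYMPTOM"),
    ]
    assert resolve_overlaps(ms) == sorted(ms)


def test_resolve_overlaps_keeps_longest():
    a = EntityMention("d", 0, 10, "x" * 10, "DISEASE")
    b = EntityMention("d", 5, 20, "x" * 15, "PROCEDURE")
    assert resolve_overlaps([a, b]) == [b]


def test_resolve_overlaps_transitive_chain():
    chain = [
        EntityMention("d", 0, 5, "aaaaa", "DISEASE"),
        EntityMention("d", 4, 9, "bbbbb", "SYMPTOM"),
        EntityMention("d", 8, 15, "ccccccc", "PROCEDURE"),
    ]
    kept = resolve_overlaps(chain)
    assert kept == [chain[2]] and kept[0].length == 7


@pytest.mark.parametrize("seed", range(10))
def test_resolve_overlaps_matches_bruteforce_oracle(seed):
    rng = random.Random(seed)
    for _ in range(50):
        mentions = random_mentions(rng, rng.randrange(0, 21))
        result = resolve_overlaps(mentions)
        assert result == _overlap_oracle(mentions)
        for a, b in zip(result, result[1:]):
            assert not a.overlaps(b)
        assert set(result) <= set(mentions)  # never invents mentions


# ---------------------------------------------------------------- merging


def test_build_merged_corpus(corpus_files):
    docs = read_documents(corpus_files["docs"])
    sources = [
        read_standoff_tsv(corpus_files["distemist"], "DISEASE", "DISTEMIST"),
        read_standoff_tsv(corpus_files["symptemist"], "SYMPTOM", "SYMPTEMIST"),
        read_standoff_tsv(corpus_files["medprocner"], "PROCEDURE", "MEDPROCNER"),
    ]
    corpus = build_merged_corpus(docs, sources, test_ids={"d2"})
    # all three documents are common; d1 simply lacks disease/procedure rows
    assert set(corpus.documents) == {"d1", "d2", "d3"}
    assert corpus.split == {"d1": "TRAIN", "d2": "TEST", "d3": "TRAIN"}
    assert len(corpus.mentions) == 8
    assert len([m for m in corpus.mentions if m.doc_id == "d1"]) == 2


def test_build_merged_corpus_empty_test_ids(corpus_files):
    docs = read_documents(corpus_files["docs"])
    sources = [
        read_standoff_tsv(corpus_files["symptemist"], "SYMPTOM", "SYMPTEMIST"),
    ]
    corpus = build_merged_corpus(docs, sources, test_ids=set())
    assert set(corpus.split.values()) == {"TRAIN"}


def test_build_merged_corpus_unknown_test_id_fatal(corpus_files):
    docs = read_documents(corpus_files["docs"])
    sources = [
        read_standoff_tsv(corpus_files["symptemist"], "SYMPTOM", "SYMPTEMIST"),
    ]
    with pytest.raises(CorpusError, match="zzz"):
        build_merged_corpus(docs, sources, test_ids={"zzz"})


def test_build_merged_corpus_resolves_cross_source_overlaps():
    doc = ClinicalDocument("d", "left renal ultrasound performed")
    dis = [EntityMention("d", 5, 10, "renal", "DISEASE", "DISTEMIST")]
    proc = [EntityMention("d", 5, 21, "renal ultrasound", "PROCEDURE", "MEDPROCNER")]
    corpus = build_merged_corpus([doc], [dis, proc], set())
    assert [m.category for m in corpus.mentions] == ["PROCEDURE"]


# -------------------------------------------------------------------- IOB


def test_to_iob_no_mentions(doc_fever):
    seq = to_iob(doc_fever, [])
    assert set(seq.labels) == {"O"}


def test_to_iob_hand_labels(doc_fever):
    m = EntityMention("d1", 0, 5, "fever", "SYMPTOM")
    assert to_iob(doc_fever, [m], categorical=True).labels == ["B-SYMPTOM", "O", "O"]
    assert to_iob(doc_fever, [m], categorical=False).labels == ["B", "O", "O"]


def test_to_iob_multi_token_mention():
    doc = ClinicalDocument("d", "heaviness in the left flank noted")
    m = EntityMention("d", 17, 27, "left flank", "SYMPTOM")
    seq = to_iob(doc, [m])
    assert seq.labels == ["O", "O", "O", "B-SYMPTOM", "I-SYMPTOM", "O"]


def test_tokenizer_separates_edge_punctuation():
    toks = tokenize("fever, chills (mild).")
    assert [t[0] for t in toks] == ["fever", ",", "chills", "(", "mild", ")", "."]
    # spans reconstruct the exact source slices
    assert all(t[0] == "fever, chills (mild)."[s:e] for t, s, e in
               [(t, t[1], t[2]) for t in toks])


@settings(derandomize=True, max_examples=100)
@given(st.data())
def test_to_iob_roundtrip_token_aligned(data):
    """Token-aligned mentions survive encode -> decode exactly."""
    words = data.draw(
        st.lists(st.sampled_from(["fever", "pain", "renal", "scan", "mild"]),
                 min_size=1, max_size=12)
    )
    text = " ".join(words)
    doc = ClinicalDocument("d", text)
    toks = tokenize(text)
    n = len(toks)
    mentions = []
    used = set()
    for _ in range(data.draw(st.integers(0, 3))):
        i = data.draw(st.integers(0, n - 1))
        j = data.draw(st.integers(i, min(i + 2, n - 1)))
        if any(k in used for k in range(i, j + 1)):
            continue
        used.update(range(i, j + 1))
        cat = data.draw(st.sampled_from(["DISEASE", "SYMPTOM", "PROCEDURE"]))
        mentions.append(
            EntityMention("d", toks[i][1], toks[j][2], text[toks[i][1]:toks[j][2]], cat)
        )
    seq = to_iob(doc, mentions)
    seq.validate()
    decoded = {(s, e, c) for s, e, c in decode_iob(seq)}
    assert decoded == {(m.start, m.end, m.category) for m in mentions}


# ------------------------------------------------------------------- stats


def test_corpus_stats_additivity(corpus_files):
    docs = read_documents(corpus_files["docs"])
    sources = [
        read_standoff_tsv(corpus_files["distemist"], "DISEASE", "DISTEMIST"),
        read_standoff_tsv(corpus_files["symptemist"], "SYMPTOM", "SYMPTEMIST"),
        read_standoff_tsv(corpus_files["medprocner"], "PROCEDURE", "MEDPROCNER"),
    ]
    corpus = build_merged_corpus(docs, sources, test_ids={"d2"})
    stats = corpus_stats(corpus)
    for source in ("DISTEMIST", "SYMPTEMIST", "MEDPROCNER"):
        rows = stats[stats.source == source].set_index("split").mentions
        assert rows["TOTAL"] == rows["TRAIN"] + rows["TEST"]
    total = stats[(stats.split == "TOTAL")].mentions.sum()
    assert total == len(corpus.mentions)
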