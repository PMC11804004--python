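import random

import pytest

from clinner.corpus import ClinicalDocument, EntityMention


@pytest.fixture
def doc_fever():
    return ClinicalDocument("d1", "fever and chills")


@pytest.fixture
def corpus_files(tmp_path):
    """A tiny on-disk corpus in the real distribution layout: a directory of
    .txt documents plus one standoff TSV per category."""
    docs = tmp_path / "docs"
    docs.mkdir()
    texts = {
        "d1": "patient presented with fever and dysuria during admission",
        "d2": "renal ultrasound showed cirrhosis without fever",
        "d3": "biopsy confirmed lymphoma after fatigue developed",
    }
    for doc_id, text in texts.items():
        (docs / f"{doc_id}.txt").write_text(text, encoding="utf-8")

    def tsv(name, rows):
        path = tmp_path / name
        lines = ["filename\tlabel\tstart_span\tend_span\ttext"]
        lines += ["\t".join(str(f) for f in row) for row in rows]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    dis = tsv(
        "distemist.tsv",
        [
            ("d2", "ENFERMEDAD", 24, 33, "cirrhosis"),
            ("d3", "ENFERMEDAD", 17, 25, "lymphoma"),
        ],
    )
    sym = tsv(
        "symptemist.tsv",
        [
            ("d1", "SINTOMA", 23, 28, "fever"),
            ("d1", "SINTOMA", 33, 40, "dysuria"),
            ("d2", "SINTOMA", 42, 47, "fever"),
            ("d3", "SINTOMA", 32, 39, "fatigue"),
        ],
    )
    proc = tsv(
        "medprocner.tsv",
        [
            ("d2", "PROCEDIMIENTO", 0, 16, "renal ultrasound"),
            ("d3", "PROCEDIMIENTO", 0, 6, "biopsy"),
        ],
    )
    return {"docs": docs, "distemist": dis, "symptemist": sym, "medprocner": proc,
            "texts": texts}


def random_mentions(rng: random.Random, n: int, doc_len: int = 120):
    """Random (possibly overlapping) mention sets for oracle comparisons."""
    cats = ("DISEASE", "SYMPTOM", "PROCEDURE")
    out = []
    for _ in range(n):
        start = rng.randrange(0, doc_len - 1)
        end = rng.randrange(start + 1, min(start + 15, doc_len) + 1)
        out.append(
            EntityMention("d", start, end, "x" * (end - start), rng.choice(cats))
        )
    return out
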