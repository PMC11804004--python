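# clinner — zero-shot clinical NER evaluation

`clinner` is an evaluation pipeline for zero-shot named entity recognition in
clinical text with generative language models. Clinical case reports are
annotated with mentions of three entity categories — **diseases**,
**symptoms**, and **medical procedures** — distributed as separate
single-category silver-standard corpora (DisTEMIST, SympTEMIST, MedProcNER).
The package is for researchers who want to measure how well an LLM, prompted
with task instructions only, recovers those mentions, and how reliably it can
emit them in a requested structure.

It provides:

- **Corpus merging** — build one multiclass corpus from per-category standoff
  annotation TSVs over a shared document set, removing cross-category span
  overlaps by keeping the longest span of each overlapping cluster, and
  emitting token-level IOB labels (`B-X`/`I-X`/`O`).
- **Prompting** — three prompt variations of increasing structural demand:
  free text, a Python-dictionary-like keyed list, and a JSON `annotations`
  array.
- **Fault-tolerant output parsing** — recover per-category entity lists from
  raw generations, tolerating bullets, unquoted keys, truncated JSON and
  prose wrappers, with strict-grammar reference parsers as oracles.
- **Two evaluation strategies** —
  *strategy 1*: for each silver surface form found (completely or partially)
  in the raw output, tag all its occurrences in the document with
  category-free B/I tags;
  *strategy 2*: parse the requested structure, then tag all document
  occurrences of each parsed entity with that category's B/I tags.
- **Scoring** — entity-level (strict span+label) and token-level
  precision/recall/F1 with micro averaging, i.e. for pooled counts
  P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); plus the valid-output
  ratio (fraction of documents whose generation parsed into ≥ 1 entity).
- **Synthetic data** — a corpus generator with planted mentions and an LLM
  simulator with controllable recall, hallucination, miscategorization,
  corruption and truncation rates, so the whole pipeline is testable offline
  and metric code can be validated by parameter recovery.

A key structural property: because both strategies only ever tag spans that
actually occur in the source document, hallucinated entities (strings absent
from the document) can never produce false positives — document grounding is
what drives the characteristically high precision of free-text evaluation.

## Worked example

Parsing a real mixtral-8x7b-instruct generation for a renal hydatid disease
case (shipped in `clinner.examples`):

```python
from clinner import examples
from clinner.parsing import parse_keyed_list, parse_json_annotations

p2 = parse_keyed_list(examples.MIXTRAL_VARIATION_2)
print(p2.status, {c: len(v) for c, v in p2.entities.items()})

p3 = parse_json_annotations(examples.MIXTRAL_VARIATION_3)
print(p3.status, p3.total_entities(), len(p3.diagnostics))
```

prints

```
PARSED {'DISEASE': 1, 'SYMPTOM': 9, 'PROCEDURE': 11}
EMPTY 0 2
```

The keyed-list generation (prompt variation 2) yields 1 disease, 9 symptoms
and 11 procedures despite the prose wrapped around the lists. The JSON
generation (variation 3) is truncated, unquoted, and mislabels its two
entities (`category: not applicable` / no category at all): the repairing
parser recovers both objects but neither has a canonical category, so the
document counts as an invalid output for the validity ratio.

End-to-end on synthetic data:

```bash
clinner simulate --out run/        # corpus + simulated generations
clinner merge --docs run/docs --distemist run/distemist.tsv \
    --symptemist run/symptemist.tsv --medprocner run/medprocner.tsv \
    --test-ids run/test_ids.txt --out run/merged
clinner evaluate --docs run/docs --mentions run/merged/mentions.jsonl \
    --outputs run/outputs.jsonl --report run/report
clinner report --report run/report --out run/report.md
```

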