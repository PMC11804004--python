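# Methods

This note documents the evaluation procedure the package implements, the
choices made where the procedure was underdetermined, and what the synthetic
experiments do and do not establish.

## The evaluation problem

Generative models prompted for zero-shot clinical NER return free text, not
span annotations. Scoring them against a span-annotated corpus therefore
requires (a) recovering entity strings from the generation and (b) aligning
those strings back onto the source document to obtain token-level IOB labels
comparable with the gold labels. Both steps are lossy and must be specified
exactly for scores to be reproducible; this package pins down every such
choice.

## Corpus construction

The unified corpus merges three single-category silver-standard annotation
sets (diseases, symptoms, medical procedures) over their common documents.
Offsets are 0-based, half-open, character-indexed on the raw decoded text —
the standoff convention. Documents define the common set; a document may
legitimately carry no annotations in some category. Because the three
sources annotate the same text independently, spans of different categories
can overlap; overlap clusters (transitive closure of pairwise span overlap)
are resolved by keeping the single longest span. Equal lengths break by
smaller start, then by fixed category priority DISEASE < SYMPTOM <
PROCEDURE; the resolution is applied globally per document, within and
across sources. The sweep implementation is tested against a brute-force
union-find clustering oracle.

Surface/offset mismatches in standoff rows are kept with a warning, trusting
offsets: silver-standard machine translations are known to be noisy, and
dropping rows would silently change the denominators. Malformed rows
(non-integer or inverted offsets) are skipped and counted.

The test split is supplied as an explicit document-id list rather than
recomputed from any external corpus, so the split is an auditable input.

**Tokenizer.** IOB labels need a tokenization; none is canonical for this
data. The package uses an offset-preserving whitespace tokenizer that peels
leading/trailing punctuation into single-character tokens, keeping silver
mention boundaries token-aligned in the common case. A token partially cut
by a mention is assigned to it iff the token's span midpoint lies inside the
mention (deterministic, warned). Token-aligned mentions round-trip exactly
through encode/decode, a property the tests check.

## Prompts

Three templates of increasing structural demand share one system preamble.
Stored templates use an unambiguous sentinel placeholder for the clinical
text (not a literal asterisked legend, which could collide with document
content) and straight ASCII quotation marks. Rendering is pure substitution.

## Parsing generations

Strategy 2 requires recovering per-category entity lists from the raw
generation. Real generations deviate from the requested structure freely,
so two lenient parsers are provided:

- **Keyed list** (variation 2): category keywords (singular/plural,
  case-insensitive, with or without braces/bullets/asterisks) introduce a
  bracketed or line-delimited list; items split on semicolons, else on
  commas outside round brackets; items are trimmed of quotes, bullets and
  trailing punctuation. Bulleted lists without brackets are accepted with a
  diagnostic.
- **JSON annotations** (variation 3): the first brace-balanced (possibly
  truncated) region containing an `annotations` key is extracted and
  repaired — single/typographic quotes normalized, bare keys and values
  quoted, trailing commas removed, unterminated strings and brackets closed
  — then read as standard JSON. The repair passes are no-ops on conforming
  input, so the lenient parser agrees exactly with `json.loads` on valid
  JSON (property-tested over randomly generated JSON values).

Entities with a missing or non-canonical category (`not applicable`, etc.)
are dropped into diagnostics, never reassigned: with three fixed scoring
categories, guessing would inject evaluator bias. Within a category,
duplicate strings are deduplicated case-insensitively keeping the first
occurrence (list semantics). When a generation restates the structure, the
first candidate region is used. A generation is a *valid output* iff at
least one canonical entity was recovered (`status == PARSED`); the validity
ratio is the per-run fraction of such documents. Parsers never raise on
arbitrary input (fuzz-tested); strict-grammar reference parsers serve as
agreement oracles on valid input.

## Alignment and tagging

Matching between entity strings and text is case-insensitive,
whitespace-normalized, at token boundaries, with edge punctuation stripped
per token — and nothing more: no stemming, no fuzzy edit distance. A
**complete** match is the full normalized term occurring at token
boundaries. A **partial** match — never defined precisely in informal
descriptions of such evaluations — is fixed here as: a proper contiguous
subsequence of the term's tokens, of length ≥ ⌈n/2⌉, containing at least
one non-stopword token (longer subsequences preferred, ties left-to-right).
The stopword list is a small fixed English function-word list shipped with
the package and overridable per call; reproducibility is preferred over
linguistic coverage. For a partial match, only occurrences of the *matched
subsequence* are tagged — tagging unmatched tokens would fabricate
evidence.

- **Strategy 1** iterates over distinct silver surface forms (instances of
  the same string are indistinguishable to string matching); each form
  found in the raw output has all its document occurrences tagged with
  category-free B/I tags.
- **Strategy 2** iterates over parsed categories and entities; each entity
  found in the document has all occurrences of the matched surface tagged
  with that category's B/I tags. Hallucinated entities contribute nothing.

Competing claimed spans are resolved greedily longest-first, ties by
position then category priority, guaranteeing deterministic, IOB-valid
output (property-tested, and checked against a brute-force
window-enumeration tagger on small documents).

## Scoring

Counts are pooled over documents and categories (micro), never averaged per
document. Entity mode requires exact span+label equality of decoded
mentions; token mode compares non-O labels positionally. Both modes are
reported because published tables of this kind rarely state the level;
entity mode is the default. F1 is the harmonic mean of pooled P and R;
zero-denominator cells score 0 with support annotated. Entity mode is
verified against an independent label-chunking reference implementation on
random sequence pairs.

## Synthetic data and what it shows

The generator emulates the corpus shape: documents of ~333 words (Gaussian,
10% s.d.) of neutral filler, with on average 3 planted single-word mentions
per category per document drawn from fixed vocabularies. Category
vocabularies, filler words and hallucination surfaces are pairwise
disjoint, so planted mentions occur exactly where bookkeeping says and
hallucinations occur nowhere — the construction that makes closed-form
predictions exact. `overlap_rate` plants longer cross-category twins to
exercise overlap resolution (exactly one survivor per pair);
`repeat_rate` re-plants a surface elsewhere in the document. A 10% test
split is assigned by default.

The simulator emits each gold mention with probability `recall_true`,
miscategorizes emitted mentions at `miscat_rate`, appends
Poisson(`halluc_rate`) invented surfaces, corrupts the envelope with
probability `corrupt_rate` (prose refusal, mangled keywords, dropped
categories, unquoted keys, unclosed brackets — the failure modes observed
in real generations), and truncates with probability `truncate_rate`. Each
error mode consumes randomness from its own stream keyed by
(seed, document, variation), so runs under one seed are coupled across
rates: raising `corrupt_rate` corrupts a superset of documents, making the
validity-ratio monotonicity check pointwise rather than merely in
expectation.

Under unique single-occurrence mentions and no envelope faults the
closed-form predictions are: strategy-2 micro precision = 1 − miscat_rate,
recall = recall_true · (1 − miscat_rate); strategy 1 is unaffected by
category errors. Parameter recovery over a 200-document corpus (~1,700
mentions; binomial s.e. ≈ 0.01) measures recall within ±0.03 of the
emission probability with precision exactly 1.

**What passing does not show.** Synthetic documents have none of the
hardness of real clinical text: no boundary ambiguity (mentions are
token-aligned single words), no near-duplicate surface forms, no
translation noise, no nested or discontinuous mentions, no genuine partial
matches. The synthetic experiments validate the *evaluation machinery* —
parsing, alignment, counting — not any claim about model quality on real
corpora. Scores on real data also depend on the silver annotations'
noise, which the pipeline deliberately passes through (offsets trusted,
warnings logged).

## Numerical and degenerate-input choices

- Empty generations and refusals are ordinary records scored as-is (recall
  suffers; nothing crashes).
- Missing (document, model, variation) outputs are scored as empty
  generations and counted.
- P, R, F1 are 0 when their denominators are 0, with support recorded.
- `valid_output_ratio` of zero documents is an error, not 0/0.
- All simulation problem sizes used in tests and the acceptance script
  (200-document recovery corpus, 40-document corruption grids, 1,000-input
  parser checks, 500-set overlap checks) were chosen to put sampling error
  well inside the asserted tolerances.

## Known limitations

- Partial-match tagging and the ⌈n/2⌉ threshold are one defensible reading
  of "complete or partial match"; other thresholds would shift recall.
- The keyed-list parser takes the first structure when a generation
  restates it; models that emit a corrected second structure are read by
  their first attempt.
- No semantic normalization (abbreviations, UMLS linking) — out of scope by
  design.
- Real-model backends (HTTP/local inference) are extension points behind
  the generation contract; only replay and simulation are shipped.
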