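# Methods

This note documents the models, conventions, and design choices behind
`frameie`, and what the synthetic test bed does and does not establish.

## Data model and conventions

Character spans are 0-based, half-open `[start, end)`, counted in Unicode
code points. For a *grounded* frame, `document.text[start:end] ==
entity_text` is an enforced invariant at `add_frame` time (strict mode,
default); deserialization uses non-strict mode so corpora annotated against
other text revisions can still be loaded and validated. Frame IDs are
unique per document; the extractors assign decimal strings `"0", "1", …`
in extraction order. Relations are undirected at the data level — direction,
where meaningful, is carried by the type string (`ADE-Drug`).

Validation *reports* rather than rejects: overlapping spans are legitimate
in clinical annotation (nested entities such as a finding inside a larger
phrase), so overlap is a warning and a report entry; only duplicate IDs,
out-of-bounds spans, and text mismatches are fatal. Redundant pairs
(identical span and text) are reported separately from overlaps, each
unordered pair exactly once.

Serialization is JSON-lines, one document object per line; unknown keys are
ignored on read and dropped on write, and `read(write(doc))` is the
identity on the record.

## Engines

All components consume one chat interface: messages in, completion out.
The `ScriptedEngine` resolves the **last user message** against an exact
map, then falls back to a FIFO queue, then raises; each call appends to a
verbatim call log, making the engine a pure function of script state and
call sequence — this is what makes call-count laws and byte-identical
replay testable. One generic `EndpointEngine` covers OpenAI-style
`/chat/completions` backends (vLLM, Ollama, llama.cpp server, hosted APIs);
per-vendor adapters were deliberately not written, since the protocol, not
the vendor, is the interface.

## Prompt templating

`{{name}}` placeholders (alphanumeric + underscore), single-pass
substitution with no recursive expansion, unused context keys allowed.
Few-shot examples are injected into the input slot as `Input: …\nOutput: …`
blocks followed by `Input: <text>\nOutput:`, so the template's schema and
format instructions stay at the top and the examples sit directly before
the text to process. There is no escape for a literal `{{`; clinical text
does not contain it, and substituted values are never re-scanned.

## Frame extraction

**Sentence splitting** is rule-based and offset-preserving: a boundary
after a run of `.`/`!`/`?` followed by whitespace, or at a newline;
leading/trailing whitespace is trimmed from each span. This is adequate for
note-style text and keeps spans exact; abbreviation-aware or learned
segmentation is out of scope.

**JSON post-processing** scans the completion for the first top-level
balanced JSON array (prose and code fences around it are tolerated), keeps
object elements with a non-empty string `entity_text`, and stringifies all
other keys into the attribute map. Element-level inconsistency is
discarded, never fatal; a wholly unparseable completion yields zero items
plus a warning. Automatic repair of truncated JSON is intentionally not
attempted.

**Grounding** maps each item to the leftmost occurrence of its entity text
not already consumed within the same call, so repeated mentions map to
successive occurrences. Matching falls back exact → case-insensitive →
whitespace-normalized (the last scans every start position, so candidates
overlapping a rejected span are still found); the stored `entity_text` is
always the document slice, preserving the grounding invariant regardless of
tier. Unmatched (hallucinated) items are dropped with a warning.

**Call economics** are part of the contract: basic = 1 call per document,
review = 2, sentence = number of sentences. The review turn sends the
initial prompt, the initial completion as an assistant message, and a fixed
review instruction; `addition` mode unions the two passes deduplicated on
`(start, end, entity_text)`, `revision` mode keeps the reviewed list only.
The sentence extractor grounds each completion within its own sentence
(region offset = sentence start), so identical mentions in different
sentences are never cross-matched; a failing sentence is skipped unless
`fail_fast` is set.

## Relation extraction

All `n(n−1)/2` unordered pairs are enumerated in canonical order (ascending
start, ties by ID). The pair context exposes `frame_1`/`frame_2` as compact
JSON and `roi_text`, the span hull of the two frames widened by a window of
200 characters per side (default; configurable) — enough context for
sentence-local clinical relations without paying for whole documents.
Expected answer keys are fixed by this package: `{"relation": bool}` for
binary (string `"true"/"false"` accepted case-insensitively) and
`{"relation_type": str}` for multiclass, with closed-set enforcement
against the hook's admissible list. The prefilter skip rule — admissible
set empty or exactly `{"No-relation"}` — is checked before any engine call,
and the declarative rule hook matches the two frames' `Type` attribute
against rule pairs in either order.

## Evaluation

Strict = identical `(start, end)` + equal label; relaxed (= lenient) = ≥1
shared character + equal label; strict match implies relaxed match. Scoring
uses a **maximum** one-to-one bipartite matching (Hopcroft–Karp via
`scipy.sparse.csgraph.maximum_bipartite_matching`) rather than greedy
pairing, so counts are order-independent and never understated; the test
suite pins it against an exhaustive assignment search at ≤6×6. Attribute
scoring compares trimmed strings case-sensitively on matched pairs and
charges unmatched frames carrying the key to their side. Relation scoring
maps predicted frame IDs through the frame matching and requires the same
unordered gold pair and type, each gold relation consumed at most once.
Zero-denominator metrics are 0.0 by definition, never an error. Exact
replication of any particular challenge scorer's tie-breaking is not
claimed.

## Visualization

Rendering is text-preserving: the text container holds exactly the document
text with `<mark>` tags interleaved, so stripping markup recovers the text
and mark count equals frame count. Overlaps that HTML cannot nest are
resolved by opening frames in `(start asc, end desc)` order and
force-closing a partially overlapping frame where its enclosing mark ends
(`clipped` class). Tooltips are plain `title` attributes; relation
connectors are drawn by a small inline script as SVG paths between anchor
midpoints, labeled with the relation type — geometry is presentational, the
testable contract is one connector element per relation referencing both
frame anchors. Pages are fully self-contained (inline CSS/JS, no network
fetches).

## Synthetic test bed

The generator emulates de-identified medication statements: each note is
`n_statements` single-sentence statements of the fixed template family
`"Started <drug> <dosage> <frequency>[ for <condition>][ but developed
<ade>]."` with gold frames (Drug with Dosage/Frequency, Condition with
Assertion, ADE) and within-statement `Condition-Drug` / `ADE-Drug`
relations. Defaults — 4 statements per note, `p_condition = 0.5`,
`p_ade = 0.3`, ~20 drugs / 10 conditions / 8 ADEs / 8 dosages / 6
frequencies — are chosen to resemble a dense medication-list note where
roughly half the prescriptions name an indication and adverse events are
common enough to exercise every relation path. Vocabulary terms contain no
sentence terminators and no term is a substring of another, so splitter and
grounder assumptions hold by construction, and expected entity counts are
derivable from the generator parameters.

`gen_script` derives the completion a perfectly-behaved model would return
for each extraction prompt (per sentence or per document), keyed by the
exact prompt string. Corruption (drop / malformed element / hallucinated
entity) uses a stream independent of note generation, and consumes three
draws per gold entity regardless of probabilities — so at a fixed corruption
seed the dropped sets are nested across `p_drop` values and strict recall
is monotonically non-increasing by construction, which the tests verify.

What passing tests show: the machinery — prompting, parsing, grounding,
pair enumeration, prefiltering, scoring, serialization, rendering — is
exact and deterministic under controlled responses. What they do not show:
extraction quality on real clinical text with a real model, which depends
on prompt quality, model capacity, and corpus idiosyncrasies (abbreviation
sentence boundaries, discontinuous or overlapping mentions, attribute
normalization) that the generator deliberately does not model.

## Problem sizes

The default verification runs use 20-document corpora (4 sentences each)
for closed-loop and degradation studies, 500 random instances for the
grounding oracle, 1000 for the matching oracle, 200 crafted completions for
the discard rule, and 50 documents for rendering fidelity — sizes at which
the exhaustive oracles are still trivially fast while covering the
combinatorics (repeated mentions, case/whitespace mangling, empty sides,
all tier fallbacks).

## Known limitations

- Sentence splitting is purely rule-based; abbreviations ("Dr. Smith")
  split incorrectly.
- Grounding cannot represent discontinuous mentions and resolves repeated
  identical mentions positionally.
- Malformed JSON is discarded, not repaired; truncated model output loses
  the whole array.
- The HTTP adapter is synchronous and single-request; no concurrency or
  retry policy.
- Binary and multiclass relation extraction share the pair-prompt scaffold;
  n-ary and cross-document relations are out of scope.
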