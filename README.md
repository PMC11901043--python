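# frameie

Building blocks for LLM-based information extraction (IE) from clinical
text: named entities with attributes ("frames"), relations between frames,
prompt development, evaluation, and visualization — designed so that every
stage of a pipeline can be developed and tested **offline**, against a
deterministic scripted engine and synthetic clinical notes, before any real
model is attached.

## Who this is for

NLP practitioners in the biomedical field who want to turn free-text
documents (de-identified clinical notes, reports) into structured records —
e.g. *drugs* with dosage and frequency, *conditions* with assertion status,
*adverse drug events (ADEs)*, and the `Condition-Drug` / `ADE-Drug`
relations between them — by prompting a large language model, without
hand-rolling the plumbing around it every time.

## The model in brief

A **frame** is one extracted entity mention: an ID, a character span
`[start, end)` into the source text, the surface text, and an attribute map
(`Type=Drug`, `Dosage=81 mg`, …). A **relation** links two frames of the
same document, optionally typed. Extraction proceeds in stages:

1. **Prompt design.** An LLM agent (the *Prompt Editor*) chats with the
   user, grounded in packaged prompt-writing guidelines per extractor kind,
   and drafts templates with `{{placeholder}}` slots.
2. **Frame extraction.** Three prompting algorithms turn a document plus
   template into frames: *basic* (one call per document), *review* (a
   second "amend and correct" turn; union or replacement), and *sentence*
   (one call per sentence — better recall and span accuracy on dense
   documents). The model answers with a JSON array; elements without a
   usable `entity_text` are discarded, and surviving entity texts are
   **grounded** to exact character offsets (leftmost unconsumed occurrence;
   exact → case-insensitive → whitespace-normalized fallback). Every stored
   frame satisfies `text[start:end] == entity_text`.
3. **Relation extraction.** Binary or multiclass classification over frame
   pairs, with a *possible-relation-types* rule hook: pairs whose admissible
   set is empty or `{"No-relation"}` are decided without any model call
   (two dosages can never be related, so no inference is spent on them).
4. **Evaluation.** Precision / recall / F1 under **strict** (identical span
   + label) or **relaxed/lenient** (≥1 overlapping character + label)
   matching, computed from a *maximum* one-to-one gold↔pred matching —
   with per-attribute and relation scoring on top.
5. **Visualization.** Standalone HTML with color-coded highlights by an
   attribute (default `Type`), attribute tooltips, and relation connectors;
   also a small local HTTP server for browsing a corpus.

Any backend speaking the OpenAI-style `/chat/completions` protocol can be
plugged in (`EndpointEngine`); the `ScriptedEngine` replays canned
prompt→completion maps so the full pipeline is testable with no model at
all.

## Worked example

Generate 5 synthetic notes with gold annotations and a matching
zero-corruption script, run the sentence extractor through the scripted
engine, and score it:

```bash
frameie synth --out-dir demo --seed 7 --n-docs 5
frameie extract --template demo/template.txt --script demo/script.json \
    --extractor sentence demo/corpus.jsonl demo/pred.jsonl
frameie evaluate --mode strict --label-key Type demo/gold.jsonl demo/pred.jsonl
```

prints

```
{"docs": 5, "out_dir": "demo"}
{"docs": 5, "frames": 37, "relations": 0, "engine_calls": 20, "warnings": 0}
                 P       R      F1
frames      1.0000  1.0000  1.0000
relations   0.0000  0.0000  0.0000
{"tp": 37, "fp": 0, "fn": 0, "precision": 1.0, "recall": 1.0, "f1": 1.0}
```

The 5 notes contain 4 sentences each, so the sentence extractor makes
exactly 20 engine calls; all 37 gold frames are recovered with exact spans
and labels (the closed-loop identity: perfect scripted responses ⇒ perfect
strict scores). This run extracted no relations, hence the zero relations
row; add `--relation multiclass --relation-template ... --rules
demo/rules.json` with a pair-level script to extract them.

Render the annotations as HTML (highlights, tooltips, relation paths):

```bash
frameie render-html --out-dir demo/html demo/gold.jsonl
```

The same pipeline runs against a live endpoint by replacing `--script` with
`--endpoint-url http://localhost:8000/v1 --model <name>`.

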