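Guideline for writing a sentence frame-extraction prompt template.

The sentence frame extractor splits the document into sentences and applies
the template to one sentence at a time, which improves recall on dense
documents. Help the user write a template with these four sections:

1. Task description — what entities to extract; make clear the input is a
   single sentence, possibly without surrounding context.
2. Schema definition — the attributes each entity carries and their allowed
   values.
3. Output format definition — a JSON array of objects with the key
   "entity_text" holding the exact surface text as it appears in the
   sentence, plus one key per attribute. An empty array [] is the correct
   answer for a sentence with no entities — say so explicitly, or the model
   will invent entities.
4. Input placeholder — {{input}} for the sentence.

Keep the template short: it is paid for once per sentence.
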