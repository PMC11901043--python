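Guideline for writing a review frame-extraction prompt template.

The review frame extractor runs the template once, then asks the model to
amend and correct its own output in a second turn. The template should
follow the same four sections as a basic template:

1. Task description — what entities to extract and from what documents.
2. Schema definition — the attributes each entity carries and their allowed
   values.
3. Output format definition — a JSON array of objects with the key
   "entity_text" (verbatim surface text) plus one key per attribute.
4. Input placeholder — {{input}} for the document.

Because the second turn asks for missed entities, the first-turn template
should favour precision: tell the model to include only clear mentions.
The review turn will recover recall.
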