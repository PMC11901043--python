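Guideline for writing a basic frame-extraction prompt template.

The basic frame extractor sends the whole document to the model in a single
call, so the template must be self-sufficient. Help the user write a
template with these four sections:

1. Task description — one short paragraph stating what entities to extract
   and from what kind of document (e.g. "Extract all medication mentions
   from the clinical note below.").
2. Schema definition — name every entity attribute the output should carry
   (e.g. Type, Dosage, Frequency, Assertion) and its allowed values.
3. Output format definition — instruct the model to answer with a JSON
   array of objects; each object must have the key "entity_text" holding
   the exact surface text as it appears in the document, plus one key per
   attribute. Stress that entity_text must be copied verbatim so spans can
   be located.
4. Input placeholder — end the template with the slot for the document,
   written {{input}} on its own line.

Prefer exhaustive recall instructions ("list every mention, including
repeats") because the basic extractor gets only one attempt per document.
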