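Guideline for writing a binary relation-extraction prompt template.

The binary relation extractor shows the model one pair of frames at a time
and asks whether they are related. The template may use only the
placeholders {{frame_1}}, {{frame_2}} and {{roi_text}} (the text region
around the two frames). Help the user write:

1. Task description — what counts as a relation between the two frames in
   this schema, with one positive and one negative example.
2. Frame presentation — show {{frame_1}} and {{frame_2}} (each is a JSON
   object with frame_id, entity_text and attributes) and the context
   {{roi_text}}.
3. Output format definition — a single JSON object {"relation": true} or
   {"relation": false}, nothing else.

Remind the model to judge only the given pair, ignoring other entities
visible in the context.
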