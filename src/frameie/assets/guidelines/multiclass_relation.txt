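Guideline for writing a multiclass relation-extraction prompt template.

The multiclass relation extractor shows the model one pair of frames at a
time and asks for the relation type. The template may use only the
placeholders {{frame_1}}, {{frame_2}} and {{roi_text}}. Help the user
write:

1. Task description — the relation inventory (e.g. Dosage-Drug, ADE-Drug,
   Condition-Drug) with a one-line definition per type, plus the answer
   "No-relation" for unrelated pairs.
2. Frame presentation — show {{frame_1}} and {{frame_2}} (JSON objects
   with frame_id, entity_text and attributes) and the context {{roi_text}}.
3. Output format definition — a single JSON object
   {"relation_type": "<one of the listed types or No-relation>"}.

Encourage the user to pair this template with a possible-relation-types
rule so pairs that can only be "No-relation" never reach the model.
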