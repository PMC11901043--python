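"""Prompt Editor: an LLM agent for drafting and refining prompt templates.

Each extractor kind ships a prompt-writing guideline and example templates
as packaged text assets.  A session starts with a fixed system prompt and a
first user turn that injects the chosen kind's guideline; the user then
iterates with the agent until a template is ready.  The module is pure
request/response — the interactive terminal loop lives in the CLI — so every
session is replayable against a scripted engine.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from .engine import ChatMessage, GenerationConfig, InferenceEngine, assistant, system, user
from .templating import list_placeholders, render

__all__ = [
    "EXTRACTOR_KINDS",
    "SYSTEM_PROMPT",
    "GuidelineAsset",
    "EditorSession",
    "load_guideline",
    "start_session",
    "step",
    "extract_template",
    "UnknownExtractorKindError",
    "NoPlaceholderError",
]

EXTRACTOR_KINDS = (
    "basic_frame",
    "review_frame",
    "sentence_frame",
    "binary_relation",
    "multiclass_relation",
)
_FRAME_KINDS = {"basic_frame", "review_frame", "sentence_frame"}

SYSTEM_PROMPT = (
    "You are an AI assistant specializing in prompt writing and improvement. "
    "Your role is to help users refine, rewrite, and generate effective "
    "prompts based on guidelines provided."
)

CHAT_TEMPLATE = (
    "# Task description\n"
    "Chat with the user following the prompt guideline below.\n"
    "# Prompt guideline\n"
    "{{prompt_guideline}}"
)


class UnknownExtractorKindError(KeyError):
    pass


class NoPlaceholderError(ValueError):
    """A frame-extraction template draft contains no input placeholder."""


@dataclass(frozen=True)
class GuidelineAsset:
    extractor_kind: str
    guideline_text: str
    example_templates: tuple[str, ...] = ()


@dataclass
class EditorSession:
    extractor_kind: str
    history: list[ChatMessage] = field(default_factory=list)


def load_guideline(extractor_kind: str) -> GuidelineAsset:
    """Load the packaged guideline for an extractor kind."""
    if extractor_kind not in EXTRACTOR_KINDS:
        raise UnknownExtractorKindError(
            f"unknown extractor kind {extractor_kind!r}; expected one of {EXTRACTOR_KINDS}"
        )
    text = (
        resources.files("frameie")
        .joinpath(f"assets/guidelines/{extractor_kind}.txt")
        .read_text(encoding="utf-8")
    )
    return GuidelineAsset(extractor_kind=extractor_kind, guideline_text=text)


def start_session(extractor_kind: str) -> EditorSession:
    """Open an editor session seeded with the system prompt and the kind's
    guideline rendered into the first user turn."""
    asset = load_guideline(extractor_kind)
    first_turn = render(CHAT_TEMPLATE, {"prompt_guideline": asset.guideline_text})
    return EditorSession(
        extractor_kind=extractor_kind,
        history=[system(SYSTEM_PROMPT), user(first_turn)],
    )


def step(
    session: EditorSession,
    user_text: str,
    engine: InferenceEngine,
    config: GenerationConfig | None = None,
) -> tuple[EditorSession, str]:
    """One chat exchange: append the user turn, get a completion, append it.

    Atomic: if the engine fails, the session is left unchanged and the error
    propagates.
    """
    candidate = session.history + [user(user_text)]
    completion = engine.chat(candidate, config)
    session.history.append(user(user_text))
    session.history.append(assistant(completion))
    return session, completion


_FENCE = re.compile(r"```[A-Za-z0-9_-]*\n(.*?)```", re.DOTALL)


def extract_template(assistant_text: str, extractor_kind: str | None = None) -> str:
    """Pull a prompt template out of an assistant reply.

    Takes the first fenced code block if present, else the whole text.
    Frame-extractor drafts must contain at least one placeholder (the input
    slot).
    """
    m = _FENCE.search(assistant_text)
    template = m.group(1) if m else assistant_text
    template = template.strip("\n")
    if extractor_kind in _FRAME_KINDS and not list_placeholders(template):
        raise NoPlaceholderError(
            "frame-extraction template must contain at least one {{...}} placeholder"
        )
    return template
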