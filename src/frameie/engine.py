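"""Chat-inference contract and engines.

All extractors and the prompt editor talk to an LLM through one interface,
:meth:`InferenceEngine.chat`: a list of role-tagged messages in, a completion
string out.  Two engines are provided:

* :class:`ScriptedEngine` — a deterministic test double that resolves each
  call from a canned script (exact match on the last user message, then a
  FIFO queue).  It makes every pipeline stage testable offline and is the
  backbone of the test suite and fixtures.
* :class:`EndpointEngine` — a generic adapter for OpenAI-style
  ``/chat/completions`` HTTP endpoints, for real inference.

Every prompt and raw completion passes through the engine unmodified and is
retained in the call log, so pipeline inputs and outputs stay fully
inspectable.
"""

from __future__ import annotations

import json
import logging
import os
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "ChatMessage",
    "GenerationConfig",
    "InferenceEngine",
    "ScriptedEngine",
    "EndpointEngine",
    "ScriptExhaustedError",
    "EndpointError",
    "user",
    "system",
    "assistant",
]

_ROLES = ("system", "user", "assistant")


class ScriptExhaustedError(RuntimeError):
    """Scripted engine has no exact match and an empty fallback queue."""


class EndpointError(RuntimeError):
    """HTTP chat endpoint failed or returned an unusable payload."""


@dataclass(frozen=True)
class ChatMessage:
    role: str
    content: str

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")


def system(content: str) -> ChatMessage:
    return ChatMessage("system", content)


def user(content: str) -> ChatMessage:
    return ChatMessage("user", content)


def assistant(content: str) -> ChatMessage:
    return ChatMessage("assistant", content)


@dataclass(frozen=True)
class GenerationConfig:
    """Backend generation parameters.

    ``temperature=0`` is the default so pipelines are reproducible where the
    backend allows it; ``extra`` is passed through to the endpoint payload
    untouched.
    """

    temperature: float = 0.0
    max_tokens: int = 1024
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.max_tokens <= 0:
            raise ValueError("max_tokens must be positive")


class InferenceEngine:
    """Uniform chat interface; subclasses implement :meth:`chat`."""

    def chat(self, messages: list[ChatMessage], config: GenerationConfig | None = None) -> str:
        raise NotImplementedError


def _last_user_content(messages: list[ChatMessage]) -> str | None:
    for msg in reversed(messages):
        if msg.role == "user":
            return msg.content
    return None


class ScriptedEngine(InferenceEngine):
    """Deterministic engine mapping prompts to canned completions.

    Resolution order: exact match of the last user message against the
    ``exact`` map, else the head of the FIFO ``queue``.  Each call appends
    one ``(messages, completion)`` entry to ``call_log``, so the engine is a
    pure function of its script state and the call sequence.
    """

    def __init__(self, exact: dict[str, str] | None = None, queue: list[str] | None = None):
        self.exact: dict[str, str] = dict(exact or {})
        self.queue: list[str] = list(queue or [])
        self.call_log: list[tuple[tuple[ChatMessage, ...], str]] = []

    def chat(self, messages: list[ChatMessage], config: GenerationConfig | None = None) -> str:
        if not messages:
            raise ValueError("messages must be non-empty")
        key = _last_user_content(messages)
        if key is not None and key in self.exact:
            completion = self.exact[key]
        elif self.queue:
            completion = self.queue.pop(0)
        else:
            raise ScriptExhaustedError(
                "no scripted completion for this prompt (no exact match, empty queue)"
            )
        self.call_log.append((tuple(messages), completion))
        return completion

    @property
    def call_count(self) -> int:
        return len(self.call_log)

    def to_script(self) -> dict:
        return {"exact": dict(self.exact), "queue": list(self.queue)}

    @classmethod
    def from_file(cls, path: str | Path) -> "ScriptedEngine":
        """Load a script file: JSON ``{"exact": {str: str}, "queue": [str]}``."""
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(exact=data.get("exact", {}), queue=data.get("queue", []))

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_script(), fh, ensure_ascii=False, indent=1)


class EndpointEngine(InferenceEngine):
    """Adapter for an OpenAI-style chat-completions HTTP endpoint.

    One adapter covers any backend speaking the de-facto standard
    ``POST {base_url}/chat/completions`` protocol (vLLM, Ollama,
    llama.cpp server, hosted APIs); the API key is read from the
    environment variable named by ``api_key_env`` and never stored.
    """

    def __init__(self, base_url: str, model: str, api_key_env: str | None = None,
                 timeout: float = 120.0):
        self.base_url = base_url.rstrip("/")
        self.model = model
        self.api_key_env = api_key_env
        self.timeout = timeout
        self.call_log: list[tuple[tuple[ChatMessage, ...], str]] = []

    def chat(self, messages: list[ChatMessage], config: GenerationConfig | None = None) -> str:
        if not messages:
            raise ValueError("messages must be non-empty")
        config = config or GenerationConfig()
        payload = {
            "model": self.model,
            "messages": [{"role": m.role, "content": m.content} for m in messages],
            "temperature": config.temperature,
            "max_tokens": config.max_tokens,
            **config.extra,
        }
        headers = {"Content-Type": "application/json"}
        if self.api_key_env:
            key = os.environ.get(self.api_key_env)
            if key:
                headers["Authorization"] = f"Bearer {key}"
        req = urllib.request.Request(
            f"{self.base_url}/chat/completions",
            data=json.dumps(payload).encode("utf-8"),
            headers=headers,
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = json.loads(resp.read().decode("utf-8"))
            completion = body["choices"][0]["message"]["content"]
        except (urllib.error.URLError, KeyError, IndexError, json.JSONDecodeError) as exc:
            raise EndpointError(f"chat endpoint {self.base_url} failed: {exc}") from exc
        self.call_log.append((tuple(messages), completion))
        return completion
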