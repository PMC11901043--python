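"""Prompt-template rendering.

Templates are plain strings with ``{{name}}`` placeholders (alphanumeric
plus underscore).  Substituted values are inserted verbatim and never
re-scanned, so there is no recursive expansion.  Unused context keys are
permitted: few-shot assembly passes a superset of what any one template
needs.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping

__all__ = [
    "PLACEHOLDER_PATTERN",
    "list_placeholders",
    "render",
    "load_template",
    "load_few_shot",
    "MissingKeyError",
    "AmbiguousBareStringError",
]

PLACEHOLDER_PATTERN = re.compile(r"\{\{([A-Za-z0-9_]+)\}\}")


class MissingKeyError(KeyError):
    """A placeholder has no entry in the rendering context."""


class AmbiguousBareStringError(ValueError):
    """A bare-string context was given but the template does not have
    exactly one placeholder."""


def list_placeholders(template: str) -> list[str]:
    """Placeholder names in first-occurrence order, deduplicated."""
    seen: list[str] = []
    for m in PLACEHOLDER_PATTERN.finditer(template):
        name = m.group(1)
        if name not in seen:
            seen.append(name)
    return seen


def render(template: str, context: Mapping[str, str] | str) -> str:
    """Substitute every placeholder in ``template``.

    ``context`` may be a mapping, or a bare string when the template has
    exactly one placeholder (the common single-input case).
    """
    names = list_placeholders(template)
    if isinstance(context, str):
        if len(names) != 1:
            raise AmbiguousBareStringError(
                f"bare-string context requires exactly 1 placeholder, template has {len(names)}"
            )
        context = {names[0]: context}
    missing = [n for n in names if n not in context]
    if missing:
        raise MissingKeyError(f"no context value for placeholder(s): {', '.join(missing)}")
    # single pass so substituted values are not re-scanned
    return PLACEHOLDER_PATTERN.sub(lambda m: str(context[m.group(1)]), template)


def load_template(path: str | Path) -> str:
    return Path(path).read_text(encoding="utf-8")


def load_few_shot(path: str | Path) -> list[dict]:
    """Load a few-shot examples file: JSON list of {"input", "output"} pairs."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, list) or not all(
        isinstance(e, dict) and "input" in e and "output" in e for e in data
    ):
        raise ValueError("few-shot file must be a JSON list of {input, output} objects")
    return data
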