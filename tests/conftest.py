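import html
import re

import pytest

from frameie.datamodel import Frame, IEDocument
from frameie.synthetic import NoteSpec, gen_corpus


def make_frame(frame_id, start, end, text="x", **attrs):
    """Frame shorthand for matcher/validation tests (text not grounded)."""
    return Frame(
        frame_id=str(frame_id),
        start=start,
        end=end,
        entity_text=text,
        attributes={k: str(v) for k, v in attrs.items()},
    )


@pytest.fixture
def aspirin_doc():
    return IEDocument(doc_id="d0", text="aspirin 81 mg")


@pytest.fixture
def small_corpus():
    """20 synthetic notes under the default study conditions."""
    spec = NoteSpec(seed=1, n_statements=4, p_condition=0.5, p_ade=0.3)
    return gen_corpus(spec, 20)


_TAG = re.compile(r"<[^>]+>")


def strip_rendered_text(page: str) -> str:
    """Recover the raw document text from a rendered HTML page."""
    from frameie.visualization import TEXT_END, TEXT_START

    start = page.index(TEXT_START) + len(TEXT_START)
    end = page.index(TEXT_END)
    return html.unescape(_TAG.sub("", page[start:end]))
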