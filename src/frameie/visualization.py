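"""Self-contained HTML rendering of annotated documents.

:func:`render_html` turns a document into one standalone HTML page: every
frame becomes an inline ``<mark>`` element wrapping exactly its text slice,
colored by a chosen attribute (``Type`` by default) and carrying all
attributes as a hover tooltip; relations are drawn as connector paths
between frame anchors by a small inline script (no network fetches, no
external assets).  The rendering is text-preserving: stripping the markup
from the text container recovers the document text exactly.

Overlapping frames cannot always nest in HTML.  Frames are opened in
``(start asc, end desc)`` order; a frame that partially overlaps an
earlier one is force-closed where its enclosing mark ends and styled with a
``clipped`` class, so every frame still yields exactly one mark element.

:func:`serve` exposes an index plus per-document pages over a local HTTP
server for quick browsing.
"""

from __future__ import annotations

import html
import json
import threading
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .datamodel import IEDocument

__all__ = ["RenderConfig", "render_html", "serve", "VizServer", "DanglingRelationError", "PortInUseError"]

DEFAULT_PALETTE = (
    "#aecbfa", "#f8b9b7", "#c8e6c9", "#ffe0a3",
    "#d7bde2", "#b2dfdb", "#f0c2e0", "#d9d9d9",
)

TEXT_START = "<!--doc-text-start-->"
TEXT_END = "<!--doc-text-end-->"


class DanglingRelationError(ValueError):
    """A relation references a frame ID absent from the document."""


class PortInUseError(OSError):
    pass


@dataclass(frozen=True)
class RenderConfig:
    """Rendering options.

    ``color_key`` selects the attribute that drives highlight colors;
    distinct values are assigned palette entries in first-occurrence order,
    cycling when exhausted.
    """

    color_key: str = "Type"
    palette: tuple[str, ...] = DEFAULT_PALETTE
    show_relations: bool = True

    def __post_init__(self) -> None:
        if not self.palette:
            raise ValueError("palette must be non-empty")


def _color_classes(doc: IEDocument, config: RenderConfig) -> dict[str, int]:
    classes: dict[str, int] = {}
    for frame in doc.frames:
        value = frame.attributes.get(config.color_key, "")
        if value not in classes:
            classes[value] = len(classes)
    return classes


def _tooltip(frame) -> str:
    lines = [f"frame_id: {frame.frame_id}"]
    lines += [f"{k}: {v}" for k, v in frame.attributes.items()]
    return "&#10;".join(html.escape(line, quote=True) for line in lines)


def _render_text(doc: IEDocument, config: RenderConfig, classes: dict[str, int]) -> str:
    """Emit the document text with mark tags, preserving the text exactly."""
    order = sorted(
        range(len(doc.frames)),
        key=lambda i: (doc.frames[i].start, -doc.frames[i].end, i),
    )
    starts: dict[int, list[int]] = {}
    for i in order:
        starts.setdefault(doc.frames[i].start, []).append(i)
    boundaries = sorted(
        {0, len(doc.text)}
        | {f.start for f in doc.frames}
        | {f.end for f in doc.frames}
    )
    out: list[str] = []
    stack: list[int] = []  # indices of open frames
    for pos, nxt in zip(boundaries, boundaries[1:] + [None]):
        # close any frame due at pos; frames above it on the stack are clipped
        while stack and any(doc.frames[i].end <= pos for i in stack):
            idx = stack.pop()
            out.append("</mark>")
        for idx in starts.get(pos, ()):
            frame = doc.frames[idx]
            clipped = stack and doc.frames[stack[-1]].end < frame.end
            cls = f"ent c{classes[frame.attributes.get(config.color_key, '')] % len(config.palette)}"
            if clipped:
                cls += " clipped"
            out.append(
                f'<mark id="frame-{html.escape(frame.frame_id, quote=True)}" '
                f'class="{cls}" title="{_tooltip(frame)}">'
            )
            stack.append(idx)
        if nxt is not None and nxt > pos:
            out.append(html.escape(doc.text[pos:nxt]))
    while stack:
        stack.pop()
        out.append("</mark>")
    return "".join(out)


_PAGE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: Georgia, serif; max-width: 60em; margin: 2em auto; line-height: 2.2; }}
mark.ent {{ padding: 0.1em 0.15em; border-radius: 0.25em; }}
mark.clipped {{ border-right: 2px dashed #666; }}
{color_css}
#legend span {{ margin-right: 1em; }}
#relations {{ margin-top: 1em; font-family: monospace; font-size: 0.9em; }}
svg#rel-overlay {{ position: absolute; top: 0; left: 0; width: 100%; height: 100%;
                   pointer-events: none; overflow: visible; }}
#doc-wrap {{ position: relative; }}
.rel-connector {{ color: #444; }}
</style>
</head>
<body>
<h2>{title}</h2>
<div id="legend">{legend}</div>
<div id="doc-wrap">
<svg id="rel-overlay"></svg>
<div id="doc-text">{text_start}{body}{text_end}</div>
</div>
{relations_html}
{relations_script}
</body>
</html>
"""

_REL_SCRIPT = """<script>
(function () {
  var svg = document.getElementById("rel-overlay");
  var wrap = document.getElementById("doc-wrap");
  var rels = %s;
  function mid(el) {
    var r = el.getBoundingClientRect(), w = wrap.getBoundingClientRect();
    return [r.left - w.left + r.width / 2, r.top - w.top];
  }
  rels.forEach(function (rel) {
    var a = document.getElementById("frame-" + rel.f1);
    var b = document.getElementById("frame-" + rel.f2);
    if (!a || !b) return;
    var p1 = mid(a), p2 = mid(b);
    var path = document.createElementNS("http://www.w3.org/2000/svg", "path");
    var cy = Math.min(p1[1], p2[1]) - 14;
    path.setAttribute("d", "M" + p1[0] + "," + p1[1] + " C" + p1[0] + "," + cy +
                      " " + p2[0] + "," + cy + " " + p2[0] + "," + p2[1]);
    path.setAttribute("fill", "none");
    path.setAttribute("stroke", "#888");
    svg.appendChild(path);
    var label = document.createElementNS("http://www.w3.org/2000/svg", "text");
    label.setAttribute("x", (p1[0] + p2[0]) / 2);
    label.setAttribute("y", cy + 4);
    label.setAttribute("font-size", "10");
    label.setAttribute("text-anchor", "middle");
    label.textContent = rel.label;
    svg.appendChild(label);
  });
})();
</script>"""


def render_html(doc: IEDocument, config: RenderConfig | None = None) -> str:
    """Render one document as a standalone HTML page.

    Raises :class:`DanglingRelationError` if any relation references a
    missing frame — run :meth:`IEDocument.validate` first to locate them.
    """
    config = config or RenderConfig()
    report = doc.validate()
    if report.dangling_relations:
        raise DanglingRelationError(
            f"relations at indices {report.dangling_relations} reference missing frames"
        )
    classes = _color_classes(doc, config)
    color_css = "\n".join(
        f"mark.c{idx % len(config.palette)} {{ background: {config.palette[idx % len(config.palette)]}; }}"
        for idx in sorted(set(v % len(config.palette) for v in classes.values()))
    )
    legend = " ".join(
        f'<span><mark class="ent c{idx % len(config.palette)}">{html.escape(value or "(none)")}</mark></span>'
        for value, idx in classes.items()
    )
    if config.show_relations:
        items = []
        for rel in doc.relations:
            label = rel.relation_type or "rel"
            items.append(
                f'<div class="rel-connector" data-frame-1="frame-{html.escape(rel.frame_1_id, quote=True)}" '
                f'data-frame-2="frame-{html.escape(rel.frame_2_id, quote=True)}">'
                f"{html.escape(rel.frame_1_id)} &mdash;[{html.escape(label)}]&mdash; "
                f"{html.escape(rel.frame_2_id)}</div>"
            )
        relations_html = '<div id="relations">' + "".join(items) + "</div>"
        rels_json = json.dumps(
            [
                {"f1": r.frame_1_id, "f2": r.frame_2_id, "label": r.relation_type or "rel"}
                for r in doc.relations
            ]
        )
        relations_script = _REL_SCRIPT % rels_json
    else:
        relations_html = ""
        relations_script = ""
    return _PAGE.format(
        title=html.escape(doc.doc_id),
        color_css=color_css,
        legend=legend,
        text_start=TEXT_START,
        body=_render_text(doc, config, classes),
        text_end=TEXT_END,
        relations_html=relations_html,
        relations_script=relations_script,
    )


@dataclass
class VizServer:
    """A running local visualization service; stop with :meth:`shutdown`."""

    httpd: ThreadingHTTPServer
    thread: threading.Thread
    port: int = field(init=False)

    def __post_init__(self) -> None:
        self.port = self.httpd.server_address[1]

    def shutdown(self) -> None:
        self.httpd.shutdown()
        self.thread.join(timeout=5)
        self.httpd.server_close()


def serve(
    docs: list[IEDocument],
    config: RenderConfig | None = None,
    port: int = 0,
    host: str = "127.0.0.1",
) -> VizServer:
    """Serve an index of documents plus per-document rendered pages.

    ``port=0`` picks a free port (reported on the returned server object).
    """
    if not docs:
        raise ValueError("serve requires at least one document")
    config = config or RenderConfig()
    by_id = {doc.doc_id: doc for doc in docs}

    index_items = "".join(
        f'<li><a href="/doc/{html.escape(doc_id, quote=True)}">{html.escape(doc_id)}</a></li>'
        for doc_id in by_id
    )
    index_page = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'><title>frameie corpus</title></head>"
        f"<body><h2>Documents ({len(by_id)})</h2><ul>{index_items}</ul></body></html>"
    )

    class Handler(BaseHTTPRequestHandler):
        def do_GET(self):  # noqa: N802 (http.server API)
            from urllib.parse import unquote

            if self.path in ("/", "/index.html"):
                body = index_page.encode("utf-8")
                self.send_response(200)
            elif self.path.startswith("/doc/"):
                doc_id = unquote(self.path[len("/doc/"):])
                if doc_id in by_id:
                    body = render_html(by_id[doc_id], config).encode("utf-8")
                    self.send_response(200)
                else:
                    body = b"<html><body><h1>404 &mdash; no such document</h1></body></html>"
                    self.send_response(404)
            else:
                body = b"<html><body><h1>404</h1></body></html>"
                self.send_response(404)
            self.send_header("Content-Type", "text/html; charset=utf-8")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def log_message(self, *args):  # quiet
            pass

    try:
        httpd = ThreadingHTTPServer((host, port), Handler)
    except OSError as exc:
        raise PortInUseError(f"cannot bind {host}:{port}: {exc}") from exc
    thread = threading.Thread(target=httpd.serve_forever, daemon=True)
    thread.start()
    return VizServer(httpd=httpd, thread=thread)
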