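"""Reader and writer for the toolkit's inline annotation XML dialect.

The dialect (documented as "IeXML-style", since no normative DTD exists)
is::

    <corpus>
      <document id="D1">
        <s id="S1">text with <e grp="PRGE" ids="P1|P2">a mention</e> ...</s>
      </document>
    </corpus>

``e`` elements may nest; a ``grp`` attribute may carry ``|``-separated
alternative groups, which expand to one span per group over the same
extent.  Offsets of the resulting spans index the markup-free sentence
text in Unicode code points, 0-based and half-open, after XML entity
resolution.  Whitespace inside ``s`` is preserved verbatim; the format
marks boundaries only and implies no tokenization.
"""

from __future__ import annotations

from xml.sax.saxutils import escape, quoteattr

from lxml import etree

from .model import (
    AnnotatedCorpus,
    Document,
    EntitySpan,
    Sentence,
    spans_compatible,
    validate_corpus,
)

__all__ = [
    "parse_iexml",
    "write_iexml",
    "IexmlError",
    "IexmlParseError",
    "IexmlSerializationError",
]


class IexmlError(ValueError):
    """Base class for inline-XML format errors."""


class IexmlParseError(IexmlError):
    """Malformed or structurally invalid input (message names line/column
    where the underlying XML parser provides them)."""


class IexmlSerializationError(IexmlError):
    """Corpus not expressible as well-formed inline XML."""


# ---------------------------------------------------------------- parsing


def _parse_entity_element(elem, offset: int, spans: list[EntitySpan]):
    # Recursively collect text and spans from an ``e`` element; returns
    # (text, new_offset).  Span order is canonicalized by Sentence.
    parts: list[str] = []
    pos = offset
    if elem.text:
        parts.append(elem.text)
        pos += len(elem.text)
    for child in elem:
        if child.tag != "e":
            raise IexmlParseError(
                f"unexpected element <{child.tag}> inside sentence markup"
            )
        text, pos = _parse_entity_element(child, pos, spans)
        parts.append(text)
        if child.tail:
            parts.append(child.tail)
            pos += len(child.tail)
    start, end = offset, pos
    grp_attr = elem.get("grp")
    if not grp_attr:
        raise IexmlParseError("entity element lacks a grp attribute")
    ids_attr = elem.get("ids")
    ids = tuple(ids_attr.split("|")) if ids_attr else ()
    for group in grp_attr.split("|"):
        spans.append(EntitySpan(start, end, group, ids))
    return "".join(parts), pos


def _parse_sentence(elem) -> Sentence:
    sid = elem.get("id")
    if sid is None:
        raise IexmlParseError("sentence element lacks an id attribute")
    spans: list[EntitySpan] = []
    parts: list[str] = []
    pos = 0
    if elem.text:
        parts.append(elem.text)
        pos += len(elem.text)
    for child in elem:
        if child.tag != "e":
            raise IexmlParseError(
                f"unexpected element <{child.tag}> in sentence {sid!r}"
            )
        text, pos = _parse_entity_element(child, pos, spans)
        parts.append(text)
        if child.tail:
            parts.append(child.tail)
            pos += len(child.tail)
    return Sentence(sid, "".join(parts), spans)


def parse_iexml(xml_text: str | bytes) -> AnnotatedCorpus:
    """Parse an inline-annotated corpus.

    Every inline entity element becomes an :class:`EntitySpan` whose
    offsets index the markup-free sentence text; element nesting becomes
    span nesting.  Raises :class:`IexmlParseError` on malformed XML
    (naming line and column), on structural errors, and on duplicate
    document or sentence ids.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise IexmlParseError(f"malformed XML: {exc}") from exc
    if root.tag != "corpus":
        raise IexmlParseError(
            f"expected <corpus> root element, found <{root.tag}>"
        )
    documents: list[Document] = []
    for doc_elem in root:
        if doc_elem.tag != "document":
            raise IexmlParseError(
                f"expected <document> under <corpus>, found <{doc_elem.tag}>"
            )
        did = doc_elem.get("id")
        if did is None:
            raise IexmlParseError("document element lacks an id attribute")
        sentences = []
        for s_elem in doc_elem:
            if s_elem.tag != "s":
                raise IexmlParseError(
                    f"expected <s> under <document>, found <{s_elem.tag}>"
                )
            sentences.append(_parse_sentence(s_elem))
        documents.append(Document(did, sentences))
    corpus = AnnotatedCorpus(documents, source_label="iexml")
    report = validate_corpus(corpus)
    id_violations = [
        v for v in report.violations if v.startswith("duplicate")
    ]
    if id_violations:
        raise IexmlParseError("; ".join(id_violations))
    return corpus


# ------------------------------------------------------------- writing


def _merge_same_extent(spans: list[EntitySpan]) -> list[EntitySpan]:
    """Collapse same-extent alternative groups into one span whose group
    is the ``|``-joined alternatives (the dialect's sibling-markup rule)."""
    merged: list[EntitySpan] = []
    by_extent: dict[tuple[int, int], list[EntitySpan]] = {}
    for span in spans:
        by_extent.setdefault((span.start, span.end), []).append(span)
    for (start, end), group_members in sorted(by_extent.items()):
        if len(group_members) == 1:
            merged.append(group_members[0])
            continue
        id_sets = {m.ids for m in group_members}
        if len(id_sets) > 1:
            raise IexmlSerializationError(
                f"same-extent spans ({start},{end}) carry differing concept "
                "ids and cannot share one inline element"
            )
        joined = "|".join(m.group for m in group_members)
        merged.append(EntitySpan(start, end, joined, group_members[0].ids))
    merged.sort(key=lambda s: (s.start, -(s.end - s.start)))
    return merged


def _emit_spans(text: str, spans: list[EntitySpan], lo: int, hi: int) -> str:
    """Emit the slice text[lo:hi] with the given (sorted, merged) spans
    rendered as nested ``e`` elements."""
    out: list[str] = []
    pos = lo
    i = 0
    while i < len(spans):
        span = spans[i]
        if span.start < pos:
            raise IexmlSerializationError(
                f"crossing overlap at span ({span.start},{span.end})"
            )
        out.append(escape(text[pos : span.start]))
        # children: subsequent spans contained in this one
        j = i + 1
        children = []
        while j < len(spans) and spans[j].start < span.end:
            if spans[j].end > span.end:
                raise IexmlSerializationError(
                    f"crossing overlap between ({span.start},{span.end}) "
                    f"and ({spans[j].start},{spans[j].end})"
                )
            children.append(spans[j])
            j += 1
        attrs = f" grp={quoteattr(span.group)}"
        if span.ids:
            attrs += f" ids={quoteattr('|'.join(span.ids))}"
        inner = _emit_spans(text, children, span.start, span.end)
        out.append(f"<e{attrs}>{inner}</e>")
        pos = span.end
        i = j
    out.append(escape(text[pos:hi]))
    return "".join(out)


def write_iexml(corpus: AnnotatedCorpus) -> str:
    """Serialize a corpus to the inline dialect.

    Nested spans emit nested elements; same-extent alternatives merge into
    one element with a ``|``-joined ``grp``.  Raises
    :class:`IexmlSerializationError` for crossing partial overlaps, which
    inline XML cannot express.
    """
    lines = ["<corpus>"]
    for document in corpus.documents:
        lines.append(f"<document id={quoteattr(document.did)}>")
        for sentence in document.sentences:
            for i, a in enumerate(sentence.entities):
                for b in sentence.entities[i + 1 :]:
                    if not spans_compatible(a, b):
                        raise IexmlSerializationError(
                            f"crossing overlap ({a.start},{a.end}) vs "
                            f"({b.start},{b.end}) in sentence "
                            f"{sentence.sid!r}"
                        )
            merged = _merge_same_extent(sentence.entities)
            body = _emit_spans(sentence.text, merged, 0, len(sentence.text))
            lines.append(f"<s id={quoteattr(sentence.sid)}>{body}</s>")
        lines.append("</document>")
    lines.append("</corpus>")
    return "\n".join(lines) + "\n"
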