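"""BIO/IOB token-stream conversion.

There is no single standardized BIO/IOB format, so three dialects are
supported explicitly:

``lean``
    whitespace-separated ``surface_TAG`` tokens, one sentence per line,
    e.g. ``the_O protein_B HZF-1_I is_O``.
``two_column``
    ``surface<TAB>TAG`` lines with blank-line sentence breaks (the CoNLL
    convention); extra columns (part-of-speech etc.) are read and
    discarded.
``xml_bio``
    ``<w iob="...">surface</w>`` elements inside ``<s>`` elements,
    optionally wrapped in ``<document>``/``<corpus>``.

Tags are B/I/O (case-insensitive), optionally with a group suffix such as
``B-protein``.  Maximal ``B I*`` runs of one group become entity spans;
sentence text is reconstructed by single-space joining (BIO input carries
no spacing information).  An orphan ``I`` — no preceding ``B``/``I`` of
the same group — is repaired to ``B`` and logged, matching conlleval-style
tolerance.  BIO cannot express nested or overlapping annotations, so
conversion from the corpus model refuses them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from xml.sax.saxutils import escape, quoteattr

from lxml import etree

from .model import AnnotatedCorpus, Document, EntitySpan, Sentence

__all__ = ["BioToken", "BioError", "parse_bio", "to_bio", "DIALECTS"]

logger = logging.getLogger(__name__)

DIALECTS = ("lean", "two_column", "xml_bio")
_TAG_LETTERS = frozenset("BIO")


class BioError(ValueError):
    """Malformed BIO input or a corpus not expressible in BIO."""


@dataclass(frozen=True)
class BioToken:
    surface: str
    tag: str          # B, I or O (normalized upper-case)
    group: str | None = None


def _split_tag(raw: str, index: int) -> tuple[str, str | None]:
    letter, _, suffix = raw.partition("-")
    letter = letter.upper()
    if letter not in _TAG_LETTERS:
        raise BioError(f"unknown tag letter {raw!r} at token {index}")
    return letter, (suffix or None)


def _lean_sentences(stream: str):
    for line in stream.splitlines():
        tokens = []
        for index, item in enumerate(line.split()):
            surface, sep, raw = item.rpartition("_")
            if not sep:
                raise BioError(
                    f"token {item!r} at index {index} lacks a _TAG suffix"
                )
            letter, group = _split_tag(raw, index)
            tokens.append(BioToken(surface, letter, group))
        yield tokens


def _two_column_sentences(stream: str):
    tokens: list[BioToken] = []
    index = 0
    for line in stream.splitlines():
        if not line.strip():
            yield tokens
            tokens, index = [], 0
            continue
        columns = line.split("\t") if "\t" in line else line.split()
        if len(columns) < 2:
            raise BioError(f"line {line!r} has no tag column")
        letter, group = _split_tag(columns[-1], index)
        tokens.append(BioToken(columns[0], letter, group))
        index += 1
    yield tokens


def _xml_bio_sentences(stream: str):
    try:
        root = etree.fromstring(stream.encode("utf-8"))
    except etree.XMLSyntaxError:
        # tolerate bare <s>/<w> fragments without a single root
        try:
            root = etree.fromstring(f"<corpus>{stream}</corpus>".encode("utf-8"))
        except etree.XMLSyntaxError as exc:
            raise BioError(f"malformed XML-BIO input: {exc}") from exc
    s_elems = [root] if root.tag == "s" else root.iter("s")
    found = False
    for s_elem in s_elems:
        found = True
        tokens = []
        for index, w in enumerate(s_elem.iter("w")):
            raw = w.get("iob")
            if raw is None:
                raise BioError(f"<w> element {index} lacks an iob attribute")
            letter, group = _split_tag(raw, index)
            tokens.append(BioToken(w.text or "", letter, group))
        yield tokens
    if not found:
        # a bare run of <w> elements is one sentence
        tokens = []
        for index, w in enumerate(root.iter("w")):
            raw = w.get("iob")
            if raw is None:
                raise BioError(f"<w> element {index} lacks an iob attribute")
            letter, group = _split_tag(raw, index)
            tokens.append(BioToken(w.text or "", letter, group))
        yield tokens


def _spans_from_tokens(
    tokens: list[BioToken], default_group: str
) -> tuple[str, list[EntitySpan]]:
    """Reconstruct sentence text (single-space joined) and spans from a
    repaired tag sequence."""
    text_parts: list[str] = []
    offsets: list[tuple[int, int]] = []
    pos = 0
    for token in tokens:
        if text_parts:
            pos += 1  # the joining space
        text_parts.append(token.surface)
        offsets.append((pos, pos + len(token.surface)))
        pos += len(token.surface)
    spans: list[EntitySpan] = []
    current: tuple[int, str] | None = None  # (start token index, group)
    for i, token in enumerate(tokens):
        group = token.group or default_group
        if token.tag == "B":
            if current is not None:
                spans.append(_close(current, i - 1, offsets))
            current = (i, group)
        elif token.tag == "I":
            if current is None or current[1] != group:
                logger.warning(
                    "orphan I tag at token %d (%r): repaired to B",
                    i,
                    token.surface,
                )
                if current is not None:
                    spans.append(_close(current, i - 1, offsets))
                current = (i, group)
        else:  # O
            if current is not None:
                spans.append(_close(current, i - 1, offsets))
                current = None
    if current is not None:
        spans.append(_close(current, len(tokens) - 1, offsets))
    return " ".join(t.surface for t in tokens), spans


def _close(current, last_index, offsets) -> EntitySpan:
    start_index, group = current
    return EntitySpan(offsets[start_index][0], offsets[last_index][1], group)


def parse_bio(
    stream: str,
    dialect: str = "lean",
    default_group: str = "PGN",
    document_id: str = "d1",
) -> AnnotatedCorpus:
    """Read a BIO/IOB token stream into the corpus model.

    Tags without a group suffix receive ``default_group``.  Empty
    sentences are skipped with a warning.  The stream becomes a single
    document whose sentences are numbered from 1.
    """
    if dialect == "lean":
        sentence_iter = _lean_sentences(stream)
    elif dialect == "two_column":
        sentence_iter = _two_column_sentences(stream)
    elif dialect == "xml_bio":
        sentence_iter = _xml_bio_sentences(stream)
    else:
        raise BioError(f"unknown BIO dialect {dialect!r}")
    sentences: list[Sentence] = []
    for tokens in sentence_iter:
        if not tokens:
            logger.warning("skipping empty sentence in BIO input")
            continue
        text, spans = _spans_from_tokens(tokens, default_group)
        sentences.append(Sentence(str(len(sentences) + 1), text, spans))
    return AnnotatedCorpus(
        [Document(document_id, sentences)], source_label=f"bio:{dialect}"
    )


# ------------------------------------------------------------- writing


def _tokenize_with_offsets(text: str) -> list[tuple[str, int, int]]:
    out = []
    pos = 0
    for token in text.split():
        start = text.index(token, pos)
        out.append((token, start, start + len(token)))
        pos = start + len(token)
    return out


def to_bio(
    corpus: AnnotatedCorpus,
    dialect: str = "lean",
    with_group: bool = True,
) -> str:
    """Write a corpus as a BIO/IOB token stream.

    The corpus must be BIO-expressible: no nested or same-extent spans,
    and every span boundary must coincide with a whitespace token
    boundary.  ``with_group`` controls B-group/I-group suffixes.
    """
    if dialect not in DIALECTS:
        raise BioError(f"unknown BIO dialect {dialect!r}")
    tagged_sentences: list[list[tuple[str, str]]] = []
    for document, sentence in corpus.iter_sentences():
        where = f"document {document.did!r} sentence {sentence.sid!r}"
        for i, a in enumerate(sentence.entities):
            for b in sentence.entities[i + 1 :]:
                if a.overlaps(b):
                    raise BioError(
                        f"nested annotation not expressible in BIO ({where})"
                    )
        tokens = _tokenize_with_offsets(sentence.text)
        boundaries = {t[1] for t in tokens} | {t[2] for t in tokens}
        tags = ["O"] * len(tokens)
        for span in sentence.entities:
            if span.start not in boundaries or span.end not in boundaries:
                raise BioError(
                    f"span ({span.start},{span.end}) splits a token ({where})"
                )
            first = True
            for i, (_, start, end) in enumerate(tokens):
                if start >= span.start and end <= span.end:
                    letter = "B" if first else "I"
                    first = False
                    tags[i] = (
                        f"{letter}-{span.group}" if with_group else letter
                    )
        tagged_sentences.append(
            [(tokens[i][0], tags[i]) for i in range(len(tokens))]
        )
    if dialect == "lean":
        return "\n".join(
            " ".join(f"{surface}_{tag}" for surface, tag in sentence)
            for sentence in tagged_sentences
        ) + "\n"
    if dialect == "two_column":
        blocks = [
            "\n".join(f"{surface}\t{tag}" for surface, tag in sentence)
            for sentence in tagged_sentences
        ]
        return "\n\n".join(blocks) + "\n"
    lines = []
    for i, sentence in enumerate(tagged_sentences, start=1):
        words = "".join(
            # lower-case the tag letter only; the group suffix keeps its case
            f"<w iob={quoteattr(tag[0].lower() + tag[1:])}>{escape(surface)}</w>"
            for surface, tag in sentence
        )
        lines.append(f"<s id={quoteattr(str(i))}>{words}</s>")
    return "<corpus>" + "".join(lines) + "</corpus>\n"
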