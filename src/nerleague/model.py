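"""Core data model for inline-annotated corpora.

An :class:`AnnotatedCorpus` is an ordered list of documents, each an ordered
list of sentences.  A sentence carries its markup-free plain text together
with typed entity spans given as character intervals into that text.  Spans
within one sentence may be disjoint, identical in extent (alternative
readings of the same mention) or properly nested; crossing partial overlaps
are not representable in inline XML and are reported as violations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "EntitySpan",
    "Sentence",
    "Document",
    "AnnotatedCorpus",
    "ValidationReport",
    "validate_corpus",
    "spans_compatible",
    "copy_corpus",
]


@dataclass(frozen=True, order=True)
class EntitySpan:
    """One annotation: a character interval plus a semantic group.

    Offsets are 0-based code-point indices into the markup-free sentence
    text; ``start`` is inclusive, ``end`` exclusive.  ``group`` is a
    semantic-group label such as ``PRGE``, ``DISO`` or ``CHEM``;  ``ids``
    optionally carries concept identifiers.
    """

    start: int
    end: int
    group: str
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.ids, tuple):
            object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "EntitySpan") -> bool:
        """Interval containment, boundaries inclusive."""
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end

    def same_extent(self, other: "EntitySpan") -> bool:
        return self.start == other.start and self.end == other.end

    def text_in(self, sentence_text: str) -> str:
        return sentence_text[self.start : self.end]


def spans_compatible(a: EntitySpan, b: EntitySpan) -> bool:
    """True unless the two spans overlap partially without nesting.

    Disjoint, same-extent and properly nested pairs are compatible; a
    crossing overlap (e.g. (0,5) against (3,8)) is not, because inline XML
    cannot express it.
    """
    if not a.overlaps(b):
        return True
    return a.contains(b) or b.contains(a)


def _span_sort_key(span: EntitySpan) -> tuple[int, int, str]:
    # outer-before-inner at equal start, then group for determinism
    return (span.start, -(span.end - span.start), span.group)


@dataclass
class Sentence:
    """A sentence: identifier, plain text and its entity spans."""

    sid: str
    text: str
    entities: list[EntitySpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entities = sorted(self.entities, key=_span_sort_key)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sentence):
            return NotImplemented
        return (
            self.sid == other.sid
            and self.text == other.text
            and sorted(self.entities) == sorted(other.entities)
        )


@dataclass
class Document:
    did: str
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class AnnotatedCorpus:
    """An ordered collection of annotated documents."""

    documents: list[Document] = field(default_factory=list)
    source_label: str = ""

    def __eq__(self, other: object) -> bool:
        # equality over texts, ids and span sets; source_label is provenance
        if not isinstance(other, AnnotatedCorpus):
            return NotImplemented
        return self.documents == other.documents

    def n_annotations(self) -> int:
        return sum(
            len(s.entities) for d in self.documents for s in d.sentences
        )

    def iter_sentences(self):
        for document in self.documents:
            for sentence in document.sentences:
                yield document, sentence


@dataclass
class ValidationReport:
    violations: list[str]
    n_annotations: int

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_corpus(corpus: AnnotatedCorpus) -> ValidationReport:
    """Check every type invariant; violations are data, not exceptions.

    The returned report also carries the total annotation count (the
    "# of annotations" column of the league table).
    """
    violations: list[str] = []
    seen_dids: set[str] = set()
    for document in corpus.documents:
        if document.did in seen_dids:
            violations.append(f"duplicate document id {document.did!r}")
        seen_dids.add(document.did)
        if not document.sentences:
            violations.append(f"document {document.did!r} has no sentences")
        seen_sids: set[str] = set()
        for sentence in document.sentences:
            loc = f"document {document.did!r} sentence {sentence.sid!r}"
            if sentence.sid in seen_sids:
                violations.append(f"duplicate sentence id in {loc}")
            seen_sids.add(sentence.sid)
            n = len(sentence.text)
            for span in sentence.entities:
                if span.start == span.end:
                    violations.append(f"empty span at {span.start} in {loc}")
                elif not (0 <= span.start < span.end <= n):
                    violations.append(
                        f"span ({span.start},{span.end}) outside text "
                        f"of length {n} in {loc}"
                    )
                if not span.group or any(c.isspace() for c in span.group):
                    violations.append(
                        f"invalid group {span.group!r} in {loc}"
                    )
            spans = sentence.entities
            for i in range(len(spans)):
                for j in range(i + 1, len(spans)):
                    a, b = spans[i], spans[j]
                    if not spans_compatible(a, b):
                        violations.append(
                            f"crossing overlap ({a.start},{a.end}) vs "
                            f"({b.start},{b.end}) in {loc}"
                        )
                    if a.same_extent(b) and a.group == b.group:
                        violations.append(
                            f"duplicate span ({a.start},{a.end},{a.group}) "
                            f"in {loc}"
                        )
    return ValidationReport(violations, corpus.n_annotations())


def copy_corpus(corpus: AnnotatedCorpus) -> AnnotatedCorpus:
    """Deep copy (spans are immutable and shared)."""
    return AnnotatedCorpus(
        documents=[
            Document(
                d.did,
                [Sentence(s.sid, s.text, list(s.entities)) for s in d.sentences],
            )
            for d in corpus.documents
        ],
        source_label=corpus.source_label,
    )
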