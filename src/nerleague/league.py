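"""Persistent league table and the synthetic GSC fixture generator.

The league table is an all-time ranked list of evaluation results.  Every
submission is appended, never overwritten, and the submitted corpus
itself is archived next to the store (content-addressed by SHA-256 of its
serialized form) so that future comparisons can reload it.  A submission
must carry a description of the annotation solution; entries without one
are rejected.  Rendering sorts by F-measure descending, breaking ties by
precision descending and then date ascending.

The fixture generator emulates a gold standard corpus at configurable
scale — multi-sentence pseudo-text documents with typed entity spans,
optional nesting — and derives a perturbed copy with controlled miss,
boundary-shift and spurious-annotation rates, together with the analytic
precision/recall a perfect evaluator should recover under exact matching.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .iexml import write_iexml
from .model import (
    AnnotatedCorpus,
    Document,
    EntitySpan,
    Sentence,
    spans_compatible,
)

__all__ = [
    "LeagueEntry",
    "LeagueStore",
    "FixtureConfig",
    "generate_fixture",
    "TABLE_COLUMNS",
]

#: Column order of the rendered league table.
TABLE_COLUMNS = (
    "User",
    "Reference file",
    "Assessment file",
    "# of annotations",
    "Precision",
    "Recall",
    "F-score",
    "Alignment type",
    "Date",
)

ALIGNMENT_TYPES = ("Exact", "Cos98", "Nested")


@dataclass
class LeagueEntry:
    """One row of the league table.

    Percent fields are stored at full precision and rendered to two
    decimals.  ``n_annotations`` counts the reference corpus (it
    describes the GSC, not the submission).  ``description`` is the
    submitter's account of the annotation solution and must be
    non-empty.
    """

    user: str
    reference_file: str
    assessment_file: str
    n_annotations: int
    precision: float
    recall: float
    f_measure: float
    alignment_type: str
    date: str = ""
    description: str = ""
    archive_path: str = ""

    def validate(self) -> None:
        if not self.description.strip():
            raise ValueError(
                "submission rejected: a description of the annotation "
                "solution is required"
            )
        if self.alignment_type not in ALIGNMENT_TYPES:
            raise ValueError(
                f"alignment_type must be one of {ALIGNMENT_TYPES}"
            )
        if not self.date:
            self.date = _dt.date.today().isoformat()
        _dt.date.fromisoformat(self.date)  # must be an ISO-8601 day

    def row(self) -> tuple[str, ...]:
        return (
            self.user,
            self.reference_file,
            self.assessment_file,
            str(self.n_annotations),
            f"{self.precision:.2f}%",
            f"{self.recall:.2f}%",
            f"{self.f_measure:.2f}%",
            self.alignment_type,
            self.date,
        )


def _sort_key(entry: LeagueEntry):
    # F desc, P desc, date asc; remaining fields make the order total so
    # insertion order never influences the rendered table
    return (
        -entry.f_measure,
        -entry.precision,
        entry.date,
        entry.user,
        entry.reference_file,
        entry.assessment_file,
        entry.recall,
    )


class LeagueStore:
    """Append-only store: one JSON record per line plus an ``archive``
    directory of submitted corpora."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.records_path = self.root / "league.jsonl"
        self.archive_dir = self.root / "archive"

    # -------------------------------------------------------- recording

    def record_submission(
        self, entry: LeagueEntry, corpus: AnnotatedCorpus
    ) -> LeagueEntry:
        """Archive the submitted corpus and append the entry.

        The corpus is written first; if archiving fails no entry is
        appended.  Returns the entry with ``archive_path`` filled in.
        """
        entry.validate()
        serialized = write_iexml(corpus)
        digest = hashlib.sha256(serialized.encode("utf-8")).hexdigest()
        self.archive_dir.mkdir(parents=True, exist_ok=True)
        archive_path = self.archive_dir / f"{digest[:16]}.xml"
        archive_path.write_text(serialized, encoding="utf-8")
        entry.archive_path = str(archive_path.relative_to(self.root))
        with self.records_path.open("a", encoding="utf-8") as handle:
            handle.write(json.dumps(asdict(entry)) + "\n")
        return entry

    # ---------------------------------------------------------- reading

    def entries(self) -> list[LeagueEntry]:
        if not self.records_path.exists():
            return []
        out = []
        with self.records_path.open(encoding="utf-8") as handle:
            for line in handle:
                if line.strip():
                    out.append(LeagueEntry(**json.loads(line)))
        return out

    def render_table(
        self, reference_filter: str | None = None
    ) -> list[LeagueEntry]:
        """Entries, optionally filtered to one reference corpus, in
        ranked order."""
        rows = self.entries()
        if reference_filter is not None:
            rows = [r for r in rows if r.reference_file == reference_filter]
        return sorted(rows, key=_sort_key)

    def to_tsv(self, reference_filter: str | None = None) -> str:
        lines = ["\t".join(TABLE_COLUMNS)]
        for entry in self.render_table(reference_filter):
            lines.append("\t".join(entry.row()))
        return "\n".join(lines) + "\n"

    def to_text(self, reference_filter: str | None = None) -> str:
        """Aligned plain-text rendering with the standard column set."""
        rows = [TABLE_COLUMNS] + [
            entry.row() for entry in self.render_table(reference_filter)
        ]
        widths = [
            max(len(row[i]) for row in rows) for i in range(len(TABLE_COLUMNS))
        ]
        return (
            "\n".join(
                "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
                for row in rows
            )
            + "\n"
        )


# ================================================== fixture generation

_FILLER_VOCAB = [f"w{i:02d}" for i in range(40)]
_ENTITY_VOCAB = [f"ent{i:02d}" for i in range(60)]


@dataclass
class FixtureConfig:
    """Parameters of the synthetic GSC and its perturbed copy.

    ``entities_per_sentence`` is the expected entity count per sentence
    (Poisson-distributed; entity-free sentences are legal).
    Perturbation rates are per-span
    probabilities; ``p_spurious`` adds, per reference span, one
    non-overlapping spurious span with that probability.  The seed is
    mandatory: the same configuration always yields identical corpora.
    """

    seed: int
    n_documents: int = 5
    sentences_per_document: int = 8
    entities_per_sentence: float = 2.0
    groups: tuple[str, ...] = ("PRGE", "DISO", "CHEM")
    nesting_probability: float = 0.0
    p_miss: float = 0.0
    p_spurious: float = 0.0
    p_shift: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nesting_probability", "p_miss", "p_spurious", "p_shift"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


def _generate_sentence(
    rng: np.random.Generator, sid: str, config: FixtureConfig
) -> Sentence:
    """One pseudo-text sentence: filler runs alternating with entity
    mentions, each mention preceded by the determiner "the" so that a
    boundary shift has a lexicon word to extend over."""
    n_entities = int(rng.poisson(config.entities_per_sentence))
    tokens: list[str] = []
    spans: list[EntitySpan] = []

    def _append_filler(k: int) -> None:
        tokens.extend(
            _FILLER_VOCAB[i] for i in rng.integers(0, len(_FILLER_VOCAB), k)
        )

    def _offset() -> int:
        return sum(len(t) + 1 for t in tokens)

    _append_filler(int(rng.integers(1, 4)))
    for _ in range(n_entities):
        tokens.append("the")
        start = _offset()
        n_mention = int(rng.integers(1, 4))
        mention = [
            _ENTITY_VOCAB[i]
            for i in rng.integers(0, len(_ENTITY_VOCAB), n_mention)
        ]
        tokens.extend(mention)
        end = start + sum(len(t) for t in mention) + (n_mention - 1)
        group = config.groups[int(rng.integers(0, len(config.groups)))]
        spans.append(EntitySpan(start, end, group))
        if (
            n_mention >= 2
            and rng.random() < config.nesting_probability
        ):
            inner_end = start + len(mention[0])
            inner_group = config.groups[
                int(rng.integers(0, len(config.groups)))
            ]
            spans.append(EntitySpan(start, inner_end, inner_group))
        _append_filler(int(rng.integers(1, 4)))
    return Sentence(sid, " ".join(tokens), spans)


def _token_boundaries(text: str) -> list[tuple[int, int]]:
    out = []
    pos = 0
    for token in text.split(" "):
        out.append((pos, pos + len(token)))
        pos += len(token) + 1
    return out


def _perturb_sentence(
    rng: np.random.Generator, sentence: Sentence, config: FixtureConfig
) -> tuple[Sentence, int, int, int]:
    """Derived submitted-side sentence; returns (sentence, kept_unshifted,
    shifted, spurious)."""
    kept: list[EntitySpan] = []
    n_shifted = 0
    for span in sentence.entities:
        if rng.random() < config.p_miss:
            continue
        if rng.random() < config.p_shift:
            # extend the start over the preceding token (the determiner
            # for top-level spans); fall back to dropping the last token;
            # never introduce a crossing overlap with the sentence's
            # other spans
            others = [s for s in sentence.entities if s is not span]
            candidates = []
            prefix = sentence.text[: span.start]
            if prefix.endswith(" "):
                prev_start = prefix[:-1].rfind(" ") + 1
                candidates.append(
                    EntitySpan(prev_start, span.end, span.group, span.ids)
                )
            if " " in span.text_in(sentence.text):
                new_end = span.start + span.text_in(sentence.text).rfind(" ")
                candidates.append(
                    EntitySpan(span.start, new_end, span.group, span.ids)
                )
            shifted = next(
                (
                    c
                    for c in candidates
                    if all(spans_compatible(c, o) for o in others)
                ),
                None,
            )
            if shifted is not None:
                kept.append(shifted)
                n_shifted += 1
            else:
                kept.append(span)
        else:
            kept.append(span)
    n_spurious = 0
    occupied = list(kept)
    boundaries = _token_boundaries(sentence.text)
    free = [
        (s, e)
        for s, e in boundaries
        if not any(
            EntitySpan(s, e, "X").overlaps(o) for o in occupied + sentence.entities
        )
    ]
    for _ in sentence.entities:
        if rng.random() < config.p_spurious:
            if not free:
                raise ValueError(
                    "no room for spurious spans: rates infeasible for this "
                    "sentence length"
                )
            index = int(rng.integers(0, len(free)))
            s, e = free.pop(index)
            group = config.groups[int(rng.integers(0, len(config.groups)))]
            occupied.append(EntitySpan(s, e, group))
            kept.append(occupied[-1])
            n_spurious += 1
    kept_unshifted = len(kept) - n_shifted - n_spurious
    return Sentence(sentence.sid, sentence.text, kept), kept_unshifted, n_shifted, n_spurious


def generate_fixture(
    config: FixtureConfig,
) -> tuple[AnnotatedCorpus, AnnotatedCorpus, dict]:
    """Generate a (reference, perturbed, expected) triple.

    The perturbed corpus deletes each reference span with ``p_miss``,
    shifts one boundary of each survivor by one token with ``p_shift``,
    and adds spurious non-overlapping spans at rate ``p_spurious`` per
    reference span.  ``expected`` holds the analytic exact-mode scores in
    percent: recall (1−p_miss)(1−p_shift)·100 and precision
    (1−p_miss)(1−p_shift)/((1−p_miss)+p_spurious)·100, in expectation.
    """
    rng = np.random.default_rng(config.seed)
    ref_documents = []
    for d in range(config.n_documents):
        sentences = [
            _generate_sentence(rng, f"s{i + 1}", config)
            for i in range(config.sentences_per_document)
        ]
        ref_documents.append(Document(f"doc{d + 1}", sentences))
    reference = AnnotatedCorpus(ref_documents, source_label="fixture-reference")

    perturbed_documents = []
    for document in ref_documents:
        new_sentences = []
        for sentence in document.sentences:
            perturbed_sentence, _, _, _ = _perturb_sentence(
                rng, sentence, config
            )
            new_sentences.append(perturbed_sentence)
        perturbed_documents.append(Document(document.did, new_sentences))
    perturbed = AnnotatedCorpus(
        perturbed_documents, source_label="fixture-perturbed"
    )

    survive = 1.0 - config.p_miss
    exact_recall = survive * (1.0 - config.p_shift)
    denominator = survive + config.p_spurious
    exact_precision = exact_recall / denominator if denominator else 0.0
    expected = {
        "precision": 100.0 * exact_precision,
        "recall": 100.0 * exact_recall,
        "n_reference": reference.n_annotations(),
        "n_submitted": perturbed.n_annotations(),
    }
    return reference, perturbed, expected
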