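"""Sentence-based and entity-based alignment of a submitted corpus
against a gold standard corpus (GSC).

Documents are paired by identifier, sentences within a document pair by
whitespace-normalized text equality, and entities within a sentence pair
by a maximum-cardinality one-to-one matching over the admissible pairs of
the selected mode:

``exact``
    boundaries coincide exactly — the standard in public challenges and
    the preferred evaluation.
``cos98``
    symmetric relaxed matching: the spans overlap positionally and either
    their token-multiset cosine similarity reaches the threshold (default
    0.98) or their symmetric token difference lies inside a small
    extension lexicon (determiners and generic heads such as "protein").
    This accepts minor boundary differences such as an added or dropped
    determiner.
``nested``
    asymmetric relaxed matching: one annotation is fully contained in the
    other, in either direction.

With group sensitivity on (the default) a non-trivial verdict also
requires equal semantic groups.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import AnnotatedCorpus, Document, EntitySpan, Sentence

__all__ = [
    "MatchConfig",
    "SentencePairing",
    "MatchedPair",
    "UnmatchedSpan",
    "MatchResult",
    "AlignmentError",
    "align_sentences",
    "match_pair",
    "align_entities",
    "align_corpora",
    "DEFAULT_EXTENSION_LEXICON",
]

MODES = ("exact", "cos98", "nested")

#: Determiners plus generic head words whose addition or omission at a
#: boundary should not count as an error under cos98 matching.
DEFAULT_EXTENSION_LEXICON = frozenset(
    {"the", "a", "an", "protein", "proteins", "gene", "genes"}
)


class AlignmentError(ValueError):
    """Unalignable inputs (duplicate ids, unpaired sentences in strict
    mode, spans outside the pairing)."""


@dataclass(frozen=True)
class MatchConfig:
    """Configuration of the matching mode and its relaxation knobs."""

    mode: str = "exact"
    extension_lexicon: frozenset[str] = DEFAULT_EXTENSION_LEXICON
    cosine_threshold: float = 0.98
    group_sensitive: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown matching mode {self.mode!r}")
        if not 0 < self.cosine_threshold <= 1:
            raise ValueError("cosine_threshold must be in (0, 1]")
        if self.mode == "cos98" and not self.extension_lexicon:
            raise ValueError("cos98 matching requires a non-empty lexicon")
        if not isinstance(self.extension_lexicon, frozenset):
            object.__setattr__(
                self, "extension_lexicon", frozenset(self.extension_lexicon)
            )


@dataclass
class SentencePairing:
    """Outcome of sentence-based alignment for one document pair."""

    pairs: list[tuple[Sentence, Sentence]] = field(default_factory=list)
    unpaired_reference: list[Sentence] = field(default_factory=list)
    unpaired_submitted: list[Sentence] = field(default_factory=list)


@dataclass(frozen=True)
class MatchedPair:
    reference: EntitySpan
    submitted: EntitySpan
    kind: str  # exact | cos98 | nested


@dataclass(frozen=True)
class UnmatchedSpan:
    """An unmatched span together with the opposite side's spans in the
    paired sentence (empty when the sentence itself was unpaired); the
    context lets the metrics layer classify the error type."""

    span: EntitySpan
    opposing: tuple[EntitySpan, ...] = ()


@dataclass
class MatchResult:
    """One-to-one entity matching: matched pairs plus the unmatched
    remainder of each side."""

    pairs: list[MatchedPair] = field(default_factory=list)
    unmatched_reference: list[UnmatchedSpan] = field(default_factory=list)
    unmatched_submitted: list[UnmatchedSpan] = field(default_factory=list)

    def extend(self, other: "MatchResult") -> None:
        self.pairs.extend(other.pairs)
        self.unmatched_reference.extend(other.unmatched_reference)
        self.unmatched_submitted.extend(other.unmatched_submitted)


# ------------------------------------------------- sentence alignment


def _normalize(text: str) -> str:
    return " ".join(text.split())


def align_sentences(
    reference: Document,
    submitted: Document,
    *,
    strict: bool = False,
    positional_fallback: bool = False,
) -> SentencePairing:
    """Pair sentences of a document pair by normalized text equality.

    Texts are compared after collapsing internal whitespace runs and
    stripping the ends; candidates are consumed in order, so repeated
    sentences pair positionally among themselves.  When text pairing
    leaves sentences unpaired, both documents have the same sentence
    count and ``positional_fallback`` is set, the leftovers are paired
    in order instead.  ``strict`` raises on any unpaired sentence.
    """
    pairing = SentencePairing()
    used = [False] * len(submitted.sentences)
    norms = [_normalize(s.text) for s in submitted.sentences]
    cursor = 0
    leftover_ref: list[Sentence] = []
    for ref_sentence in reference.sentences:
        target = _normalize(ref_sentence.text)
        found = None
        for j in range(cursor, len(submitted.sentences)):
            if not used[j] and norms[j] == target:
                found = j
                break
        if found is None:
            leftover_ref.append(ref_sentence)
        else:
            used[found] = True
            pairing.pairs.append((ref_sentence, submitted.sentences[found]))
            cursor = found + 1
    leftover_sub = [
        s for j, s in enumerate(submitted.sentences) if not used[j]
    ]
    if (
        positional_fallback
        and (leftover_ref or leftover_sub)
        and len(reference.sentences) == len(submitted.sentences)
        and len(leftover_ref) == len(leftover_sub)
    ):
        pairing.pairs.extend(zip(leftover_ref, leftover_sub))
        leftover_ref, leftover_sub = [], []
    pairing.unpaired_reference = leftover_ref
    pairing.unpaired_submitted = leftover_sub
    if strict and (pairing.unpaired_reference or pairing.unpaired_submitted):
        sids = [s.sid for s in pairing.unpaired_reference] + [
            s.sid for s in pairing.unpaired_submitted
        ]
        raise AlignmentError(f"unpaired sentences: {', '.join(sids)}")
    return pairing


# ----------------------------------------------------- pair matching


def _tokens(span: EntitySpan, text: str) -> list[str]:
    return span.text_in(text).lower().split()


def _token_cosine(a: list[str], b: list[str]) -> float:
    """Cosine similarity between token multisets."""
    ca, cb = Counter(a), Counter(b)
    dot = sum(ca[t] * cb[t] for t in ca)
    norm = math.sqrt(sum(v * v for v in ca.values())) * math.sqrt(
        sum(v * v for v in cb.values())
    )
    return dot / norm if norm else 0.0


def _match_flags(
    a: EntitySpan,
    a_text: str,
    b: EntitySpan,
    b_text: str,
    config: MatchConfig,
) -> tuple[bool, bool, bool]:
    """(is_exact, is_cos98, is_nested) for one span pair."""
    if config.group_sensitive and a.group != b.group:
        return False, False, False
    is_exact = a.same_extent(b)
    is_nested = a.contains(b) or b.contains(a)
    is_cos98 = False
    if a.overlaps(b):
        ta, tb = _tokens(a, a_text), _tokens(b, b_text)
        if _token_cosine(ta, tb) >= config.cosine_threshold:
            is_cos98 = True
        else:
            ca, cb = Counter(ta), Counter(tb)
            diff = {
                t
                for t in set(ca) | set(cb)
                if ca.get(t, 0) != cb.get(t, 0)
            }
            is_cos98 = diff <= config.extension_lexicon
    # exact boundaries imply both relaxations
    if is_exact:
        is_cos98 = is_nested = True
    return is_exact, is_cos98, is_nested


def match_pair(
    a: EntitySpan,
    a_text: str,
    b: EntitySpan,
    b_text: str,
    config: MatchConfig,
) -> str:
    """Verdict for one span pair: the strongest of
    ``exact`` > ``cos98`` > ``nested``, else ``no-match``."""
    is_exact, is_cos98, is_nested = _match_flags(a, a_text, b, b_text, config)
    if is_exact:
        return "exact"
    if is_cos98:
        return "cos98"
    if is_nested:
        return "nested"
    return "no-match"


def _admissible(flags: tuple[bool, bool, bool], mode: str) -> bool:
    is_exact, is_cos98, is_nested = flags
    if mode == "exact":
        return is_exact
    if mode == "cos98":
        return is_cos98
    return is_nested


# ----------------------------------------------------- entity alignment

# Cost encoding for the assignment problem: cardinality dominates the
# exact-edge preference, which dominates total start-offset distance.
_CARDINALITY = 1e12
_NON_EXACT_PENALTY = 1e6
_DISTANCE_CAP = 1e4 - 1  # keeps summed distances below one exact-edge step


def _match_sentence_pair(
    ref_sentence: Sentence,
    sub_sentence: Sentence,
    config: MatchConfig,
) -> MatchResult:
    ref_spans = ref_sentence.entities
    sub_spans = sub_sentence.entities
    result = MatchResult()
    if not ref_spans or not sub_spans:
        result.unmatched_reference = [
            UnmatchedSpan(s, tuple(sub_spans)) for s in ref_spans
        ]
        result.unmatched_submitted = [
            UnmatchedSpan(s, tuple(ref_spans)) for s in sub_spans
        ]
        return result
    n, m = len(ref_spans), len(sub_spans)
    cost = np.zeros((n, m))
    flags = {}
    for i, a in enumerate(ref_spans):
        for j, b in enumerate(sub_spans):
            f = _match_flags(a, ref_sentence.text, b, sub_sentence.text, config)
            flags[i, j] = f
            if _admissible(f, config.mode):
                distance = min(abs(a.start - b.start), _DISTANCE_CAP)
                penalty = 0.0 if f[0] else _NON_EXACT_PENALTY
                cost[i, j] = -_CARDINALITY + penalty + distance
    rows, cols = linear_sum_assignment(cost)
    matched_ref, matched_sub = set(), set()
    for i, j in zip(rows, cols):
        if cost[i, j] >= 0:  # inadmissible filler assignment
            continue
        f = flags[i, j]
        kind = "exact" if f[0] else ("cos98" if config.mode == "cos98" else "nested")
        result.pairs.append(MatchedPair(ref_spans[i], sub_spans[j], kind))
        matched_ref.add(i)
        matched_sub.add(j)
    result.unmatched_reference = [
        UnmatchedSpan(s, tuple(sub_spans))
        for i, s in enumerate(ref_spans)
        if i not in matched_ref
    ]
    result.unmatched_submitted = [
        UnmatchedSpan(s, tuple(ref_spans))
        for j, s in enumerate(sub_spans)
        if j not in matched_sub
    ]
    return result


def align_entities(
    pairing: SentencePairing, config: MatchConfig
) -> MatchResult:
    """Maximum-cardinality one-to-one entity matching over a sentence
    pairing.

    Per sentence pair the matching is computed exactly; among maximum
    matchings, exact-boundary edges are preferred, then smaller total
    start-offset distance, so the result is deterministic and independent
    of annotation order.  Entities of unpaired sentences are wholly
    unmatched.
    """
    result = MatchResult()
    for ref_sentence, sub_sentence in pairing.pairs:
        result.extend(_match_sentence_pair(ref_sentence, sub_sentence, config))
    for sentence in pairing.unpaired_reference:
        result.unmatched_reference.extend(
            UnmatchedSpan(s) for s in sentence.entities
        )
    for sentence in pairing.unpaired_submitted:
        result.unmatched_submitted.extend(
            UnmatchedSpan(s) for s in sentence.entities
        )
    return result


def align_corpora(
    reference: AnnotatedCorpus,
    submitted: AnnotatedCorpus,
    config: MatchConfig | None = None,
    *,
    strict: bool = False,
    positional_fallback: bool = False,
) -> MatchResult:
    """Full corpus-level alignment: documents paired by id, then
    sentence and entity alignment, with counts pooled across the corpus
    (micro-averaging)."""
    config = config or MatchConfig()
    sub_docs: dict[str, Document] = {}
    for document in submitted.documents:
        if document.did in sub_docs:
            raise AlignmentError(f"duplicate document id {document.did!r}")
        sub_docs[document.did] = document
    seen_ref: set[str] = set()
    result = MatchResult()
    for ref_doc in reference.documents:
        if ref_doc.did in seen_ref:
            raise AlignmentError(f"duplicate document id {ref_doc.did!r}")
        seen_ref.add(ref_doc.did)
        sub_doc = sub_docs.pop(ref_doc.did, None)
        if sub_doc is None:
            for sentence in ref_doc.sentences:
                result.unmatched_reference.extend(
                    UnmatchedSpan(s) for s in sentence.entities
                )
            continue
        pairing = align_sentences(
            ref_doc,
            sub_doc,
            strict=strict,
            positional_fallback=positional_fallback,
        )
        result.extend(align_entities(pairing, config))
    for sub_doc in sub_docs.values():  # submitted documents with no reference
        for sentence in sub_doc.sentences:
            result.unmatched_submitted.extend(
                UnmatchedSpan(s) for s in sentence.entities
            )
    return result
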