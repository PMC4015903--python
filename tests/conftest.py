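"""Shared fixtures and generators for the test suite.

All corpora are generated programmatically; nothing is loaded from disk.
"""

from __future__ import annotations

import random

import pytest

from nerleague.model import AnnotatedCorpus, Document, EntitySpan, Sentence

GROUPS = ("PRGE", "DISO", "CHEM")


def random_sentence(rng: random.Random, sid: str, allow_nesting: bool = True) -> Sentence:
    """A random pseudo-text sentence with compatible (nested or disjoint)
    spans, used by round-trip and invariant tests."""
    n_tokens = rng.randint(3, 12)
    tokens = [f"t{rng.randint(0, 30):02d}" for _ in range(n_tokens)]
    text = " ".join(tokens)
    bounds = []
    pos = 0
    for token in tokens:
        bounds.append((pos, pos + len(token)))
        pos += len(token) + 1
    spans: list[EntitySpan] = []
    for _ in range(rng.randint(0, 4)):
        i = rng.randrange(n_tokens)
        j = rng.randrange(i, min(n_tokens, i + 3))
        candidate = EntitySpan(
            bounds[i][0], bounds[j][1], rng.choice(GROUPS)
        )
        ok = True
        for existing in spans:
            if candidate.overlaps(existing):
                if not (
                    candidate.contains(existing) or existing.contains(candidate)
                ):
                    ok = False
                    break
                if not allow_nesting:
                    ok = False
                    break
            if (
                existing.same_extent(candidate)
                and existing.group == candidate.group
            ):
                ok = False
                break
        if ok:
            spans.append(candidate)
    return Sentence(sid, text, spans)


def random_corpus(
    seed: int, n_documents: int = 2, n_sentences: int = 3, allow_nesting: bool = True
) -> AnnotatedCorpus:
    rng = random.Random(seed)
    return AnnotatedCorpus(
        [
            Document(
                f"d{d}",
                [
                    random_sentence(rng, f"s{i}", allow_nesting)
                    for i in range(n_sentences)
                ],
            )
            for d in range(n_documents)
        ]
    )


@pytest.fixture
def hzf1_corpus() -> AnnotatedCorpus:
    """'the HZF-1 protein is' with one PRGE span over the mention."""
    return AnnotatedCorpus(
        [
            Document(
                "d1",
                [Sentence("1", "the HZF-1 protein is", [EntitySpan(4, 9, "PRGE")])],
            )
        ]
    )


@pytest.fixture
def nested_corpus() -> AnnotatedCorpus:
    """'left lung cancer treatment' with a disease span nesting an
    anatomy span."""
    return AnnotatedCorpus(
        [
            Document(
                "d1",
                [
                    Sentence(
                        "1",
                        "left lung cancer treatment",
                        [EntitySpan(0, 16, "DISO"), EntitySpan(0, 9, "ANAT")],
                    )
                ],
            )
        ]
    )
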