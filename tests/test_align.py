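"""Sentence pairing, span-pair verdicts and one-to-one entity matching.

The entity matcher is cross-checked against an independent brute-force
oracle that enumerates all one-to-one assignments.
"""

import random

import pytest

from nerleague.align import (
    AlignmentError,
    MatchConfig,
    SentencePairing,
    align_corpora,
    align_entities,
    align_sentences,
    match_pair,
    _match_flags,
    _admissible,
)
from nerleague.model import Document, EntitySpan, Sentence

from conftest import random_corpus


# ------------------------------------------------------------- oracle


def brute_force_max_matching(ref_spans, sub_spans, admissible) -> int:
    """Maximum one-to-one matching cardinality by exhaustive search.

    ``admissible(i, j)`` says whether reference span i may pair with
    submitted span j.  Independent of the production matcher: plain
    recursion over assignments.
    """

    def best(i: int, used: frozenset) -> int:
        if i == len(ref_spans):
            return 0
        top = best(i + 1, used)  # leave span i unmatched
        for j in range(len(sub_spans)):
            if j not in used and admissible(i, j):
                top = max(top, 1 + best(i + 1, used | {j}))
        return top

    return best(0, frozenset())


def random_span_set(rng: random.Random, n: int, text_len: int):
    spans = []
    for _ in range(n):
        start = rng.randrange(0, text_len - 1)
        end = rng.randrange(start + 1, min(text_len, start + 8) + 1)
        spans.append(EntitySpan(start, end, rng.choice(["PRGE", "DISO"])))
    # deduplicate (identical spans are illegal within one sentence)
    return list(dict.fromkeys(spans))


# ------------------------------------------------- sentence alignment


class TestAlignSentences:
    def make(self, texts, prefix="s"):
        return Document(
            "d1",
            [Sentence(f"{prefix}{i}", t) for i, t in enumerate(texts)],
        )

    def test_identical_documents_fully_paired(self):
        texts = ["one two", "three four", "five"]
        pairing = align_sentences(self.make(texts), self.make(texts, "x"))
        assert len(pairing.pairs) == 3
        assert not pairing.unpaired_reference
        assert not pairing.unpaired_submitted

    def test_whitespace_differences_still_pair(self):
        ref = self.make(["one two three"])
        sub = self.make(["  one  two   three "])
        pairing = align_sentences(ref, sub)
        assert len(pairing.pairs) == 1

    def test_missing_sentence_leaves_unpaired_reference(self):
        ref = self.make(["a a", "b b", "c c"])
        sub = self.make(["a a", "c c"])
        pairing = align_sentences(ref, sub)
        assert len(pairing.pairs) == 2
        assert [s.text for s in pairing.unpaired_reference] == ["b b"]

    def test_strict_mode_raises_on_unpaired(self):
        ref = self.make(["a a", "b b"])
        sub = self.make(["a a"])
        with pytest.raises(AlignmentError, match="unpaired"):
            align_sentences(ref, sub, strict=True)

    def test_positional_fallback_requires_equal_counts(self):
        ref = self.make(["a a", "b b"])
        sub = self.make(["a a", "B B"])
        loose = align_sentences(ref, sub, positional_fallback=True)
        assert len(loose.pairs) == 2
        uneven = align_sentences(
            ref, self.make(["B B"]), positional_fallback=True
        )
        assert len(uneven.pairs) == 0

    def test_repeated_sentences_pair_in_order(self):
        ref = self.make(["x y", "x y"])
        sub = Document(
            "d1", [Sentence("a", "x y"), Sentence("b", "x y")]
        )
        pairing = align_sentences(ref, sub)
        assert [(r.sid, s.sid) for r, s in pairing.pairs] == [
            ("s0", "a"),
            ("s1", "b"),
        ]


# ----------------------------------------------------- pair verdicts


class TestMatchPair:
    TEXT = "the HZF-1 protein is"

    def test_identical_spans_exact(self):
        a = EntitySpan(4, 9, "PRGE")
        assert match_pair(a, self.TEXT, a, self.TEXT, MatchConfig()) == "exact"

    def test_determiner_and_head_extension_is_cos98(self):
        # gold "HZF-1" vs submitted "the HZF-1 protein"
        gold = EntitySpan(4, 9, "PRGE")
        submitted = EntitySpan(0, 17, "PRGE")
        verdict = match_pair(
            gold, self.TEXT, submitted, self.TEXT, MatchConfig(mode="cos98")
        )
        assert verdict == "cos98"

    def test_containment_without_lexicon_is_nested_only(self):
        text = "left lung cancer treatment"
        outer = EntitySpan(0, 26, "DISO")
        inner = EntitySpan(5, 16, "DISO")  # "lung cancer"
        config = MatchConfig(mode="nested")
        assert match_pair(outer, text, inner, text, config) == "nested"
        flags = _match_flags(outer, text, inner, text, config)
        assert not flags[1]  # difference {left, treatment} not in lexicon

    def test_disjoint_spans_no_match(self):
        a = EntitySpan(0, 3, "PRGE")
        b = EntitySpan(10, 17, "PRGE")
        assert match_pair(a, self.TEXT, b, self.TEXT, MatchConfig()) == "no-match"

    def test_group_sensitivity(self):
        a = EntitySpan(4, 9, "PRGE")
        b = EntitySpan(4, 9, "DISO")
        assert match_pair(a, self.TEXT, b, self.TEXT, MatchConfig()) == "no-match"
        insensitive = MatchConfig(group_sensitive=False)
        assert match_pair(a, self.TEXT, b, self.TEXT, insensitive) == "exact"

    def test_cos98_is_symmetric(self):
        rng = random.Random(42)
        text = " ".join(f"tk{i}" for i in range(20))
        config = MatchConfig(mode="cos98")
        for _ in range(200):
            spans = random_span_set(rng, 2, len(text))
            if len(spans) < 2:
                continue
            a, b = spans[0], spans[1]
            ab = match_pair(a, text, b, text, config)
            ba = match_pair(b, text, a, text, config)
            assert (ab == "cos98") == (ba == "cos98")

    def test_exact_implies_relaxed_flags(self):
        a = EntitySpan(4, 9, "PRGE")
        flags = _match_flags(a, self.TEXT, a, self.TEXT, MatchConfig())
        assert flags == (True, True, True)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown matching mode"):
            MatchConfig(mode="fuzzy")

    def test_cosine_threshold_bounds(self):
        with pytest.raises(ValueError):
            MatchConfig(cosine_threshold=0.0)


# ------------------------------------------------- entity alignment


def pairing_of(ref_spans, sub_spans, text_len=80):
    text = "x" * text_len
    ref = Sentence("r1", text, ref_spans)
    sub = Sentence("r1", text, sub_spans)
    return SentencePairing(pairs=[(ref, sub)])


class TestAlignEntities:
    def test_exact_preferred_over_nested(self):
        ref = [EntitySpan(10, 20, "PRGE")]
        sub = [EntitySpan(10, 20, "PRGE"), EntitySpan(5, 25, "PRGE")]
        result = align_entities(pairing_of(ref, sub), MatchConfig(mode="nested"))
        assert len(result.pairs) == 1
        assert result.pairs[0].submitted == EntitySpan(10, 20, "PRGE")
        assert result.pairs[0].kind == "exact"
        assert [u.span for u in result.unmatched_submitted] == [
            EntitySpan(5, 25, "PRGE")
        ]

    def test_two_exact_pairs(self):
        spans = [EntitySpan(0, 5, "PRGE"), EntitySpan(10, 15, "PRGE")]
        result = align_entities(pairing_of(spans, list(spans)), MatchConfig())
        assert len(result.pairs) == 2
        assert not result.unmatched_reference
        assert not result.unmatched_submitted

    def test_one_to_one_no_double_matching(self):
        # one submitted span containing two reference spans may match
        # only one of them
        ref = [EntitySpan(0, 5, "PRGE"), EntitySpan(6, 11, "PRGE")]
        sub = [EntitySpan(0, 11, "PRGE")]
        result = align_entities(pairing_of(ref, sub), MatchConfig(mode="nested"))
        assert len(result.pairs) == 1
        assert len(result.unmatched_reference) == 1

    def test_unpaired_sentences_fully_unmatched(self):
        ref = Sentence("1", "a b", [EntitySpan(0, 1, "PRGE")])
        pairing = SentencePairing(unpaired_reference=[ref])
        result = align_entities(pairing, MatchConfig())
        assert [u.span for u in result.unmatched_reference] == ref.entities

    def test_order_independence(self):
        rng = random.Random(5)
        text_len = 60
        ref = random_span_set(rng, 5, text_len)
        sub = random_span_set(rng, 5, text_len)
        base = align_entities(pairing_of(ref, sub, text_len), MatchConfig(mode="nested"))
        rng.shuffle(ref)
        rng.shuffle(sub)
        permuted = align_entities(
            pairing_of(ref, sub, text_len), MatchConfig(mode="nested")
        )
        assert sorted(
            (p.reference, p.submitted) for p in base.pairs
        ) == sorted((p.reference, p.submitted) for p in permuted.pairs)

    @pytest.mark.parametrize("mode", ["exact", "cos98", "nested"])
    def test_cardinality_matches_brute_force(self, mode):
        rng = random.Random(314)
        config = MatchConfig(mode=mode)
        text_len = 40
        text = "ab cd ef gh ij kl mn op qr st uv wx yz"  # token structure
        for _ in range(120):
            ref = random_span_set(rng, rng.randint(0, 6), len(text))
            sub = random_span_set(rng, rng.randint(0, 6), len(text))
            ref_sentence = Sentence("1", text, [])
            sub_sentence = Sentence("1", text, [])
            # bypass compatibility canonicalization: spans fed directly
            ref_sentence.entities = ref
            sub_sentence.entities = sub
            pairing = SentencePairing(pairs=[(ref_sentence, sub_sentence)])
            result = align_entities(pairing, config)

            def admissible(i, j):
                return _admissible(
                    _match_flags(ref[i], text, sub[j], text, config),
                    config.mode,
                )

            expected = brute_force_max_matching(ref, sub, admissible)
            assert len(result.pairs) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_relaxation_monotonicity(self, seed):
        corpus = random_corpus(seed)
        other = random_corpus(seed + 1000)
        # same documents/sentence texts are required for pairing: reuse
        # texts of `corpus` with spans of `other`
        for ref_doc, alt_doc in zip(corpus.documents, other.documents):
            for ref_sentence, alt_sentence in zip(
                ref_doc.sentences, alt_doc.sentences
            ):
                alt_sentence.text = ref_sentence.text
        tp = {}
        for mode in ("exact", "cos98", "nested"):
            result = align_corpora(corpus, other, MatchConfig(mode=mode))
            tp[mode] = len(result.pairs)
        assert tp["exact"] <= tp["cos98"]
        assert tp["exact"] <= tp["nested"]


class TestAlignCorpora:
    def test_missing_document_all_false_negative(self):
        ref = random_corpus(1, n_documents=2)
        sub = random_corpus(1, n_documents=1)
        result = align_corpora(ref, sub)
        missing = ref.documents[1]
        n_missing = sum(len(s.entities) for s in missing.sentences)
        assert (
            len(result.unmatched_reference)
            >= n_missing
        )

    def test_identity_gives_perfect_matching(self):
        corpus = random_corpus(9)
        result = align_corpora(corpus, corpus)
        assert not result.unmatched_reference
        assert not result.unmatched_submitted
        assert len(result.pairs) == corpus.n_annotations()
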