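# Methods

## The evaluation model

`nerleague` scores a submitted annotated corpus against a gold standard
corpus (GSC) at the entity level. The unit of comparison is the typed
span: a character interval within a sentence plus a semantic-group label
(e.g. PRGE, DISO, CHEM) and optional concept identifiers. Scores are
micro-averaged: true positives, false positives and false negatives are
pooled over all sentences and documents before precision, recall and the
balanced F-measure are computed. Macro-averaging per document was
deliberately not implemented; pooled counting is the convention of
entity-level challenge evaluations and keeps scores independent of how a
corpus is split into documents.

Alignment runs in three stages, each with fixed, documented tie-breaks
so that results are deterministic and independent of annotation order —
a requirement for a leaderboard.

1. **Document pairing** by exact identifier equality. Reference
   documents with no submitted counterpart contribute all their spans as
   false negatives; surplus submitted documents contribute false
   positives.
2. **Sentence pairing** by text equality after whitespace normalization
   (internal runs collapsed, ends stripped), consumed in document order
   so that repeated sentences pair positionally among themselves.
   Pairing is text-based rather than offset-based because submitted
   corpora are typically re-serialized and byte offsets are not
   preserved. A positional fallback (pair leftovers in order) exists
   behind a flag and only applies when both documents have the same
   sentence count. Approximate (edit-distance) sentence alignment is out
   of scope: reference and submission are by construction the same
   abstracts.
3. **Entity matching** per sentence pair: a maximum-cardinality
   one-to-one matching over the bipartite graph of mode-admissible span
   pairs, computed exactly with the Hungarian algorithm
   (`scipy.optimize.linear_sum_assignment`). Preferences among maximum
   matchings are encoded lexicographically in the edge costs: first
   maximize the number of matched pairs, then the number of
   exact-boundary pairs, then minimize total start-offset distance
   (capped per edge so the levels cannot interact). A greedy first-come
   matcher would have been order-dependent; the assignment formulation
   is not, and is cross-checked in the test suite against an independent
   brute-force enumeration oracle on hundreds of random instances.

## Matching modes

- **exact** — identical (start, end). The default mode, being the
  standard in public challenges.
- **cos98** — symmetric boundary-tolerant matching. The historical
  definition is only characterized behaviourally ("minor differences in
  their boundaries, such as an added determiner or 'protein'"), so the
  implemented criterion is a documented interpretation: the spans must
  overlap positionally, and either the cosine similarity of their token
  multisets (lower-cased, whitespace-tokenized) reaches the threshold
  (default 0.98) or their symmetric token difference is contained in an
  extension lexicon. A pure 0.98 cosine alone would reject the motivating
  example — "HZF-1" vs "HZF-1 protein" has token cosine ≈ 0.707 — hence
  the dual criterion. The shipped lexicon is the determiners
  {the, a, an} plus the generic heads {protein, proteins, gene, genes};
  it is a configurable parameter, not a claim about the original system.
  Whether the original measure operated on characters or tokens, and
  whether "98" was a cosine percent, is undocumented; this
  implementation's choice is recorded here as an interpretation.
- **nested** — one interval fully contains the other (boundaries
  inclusive), in either direction. The measure is asymmetric in
  interpretation (which side subsumes which), but counting is by matched
  pairs for both precision and recall in all modes.

Exact boundaries imply both relaxations; a pair's verdict reports the
strongest applicable kind in the order exact > cos98 > nested. Mode
admissibility is decided from the individual criteria, not from the
reported verdict, so a pair that is both cos98- and nested-admissible
counts in either mode. With `group_sensitive` on (default) all verdicts
additionally require equal groups; the off switch supports
group-agnostic span evaluation.

## Error taxonomy

Each unmatched span is classified into exactly one type, using the
opposing side's spans in the paired sentence: `group_mismatch` if some
opposing span covers the same extent with a different group,
`boundary_mismatch` if some opposing span overlaps, otherwise `missed`
(gold side) or `spurious` (submitted side). The conservation identities
tp + fn = |reference spans| and tp + fp = |submitted spans| hold by
construction and are asserted property-style in the tests.

Zero denominators (empty corpus on either side) yield P = R = F = 0 and
the report is flagged as an empty evaluation rather than silently
returned. F is balanced F1 only; no F-beta.

## Inline XML dialect

No normative DTD for the historical inline format is available, so the
package defines a minimal dialect and documents it as "IeXML-style":
`corpus` > `document id=` > `s id=`, with mixed text and nestable
`e grp= ids=` elements. Offsets are 0-based, half-open, in Unicode code
points of the entity-markup-free sentence text after XML entity
resolution — this must be fixed for exact matching to be well defined.
Within one sentence, spans are disjoint, same-extent or properly nested;
crossing partial overlaps (the "BIBI vs BIIB" situation when both
readings coexist) are not expressible in well-formed inline XML, are
rejected at parse time by construction and raise a serialization error
on writing — such data needs separate annotation layers, one corpus file
per layer. Same-extent alternatives serialize as a single element with a
`|`-joined `grp`; if such spans carry different concept-id lists the
corpus is not losslessly serializable and an error is raised rather than
merging the ids. Standoff annotation input is a non-goal.

## BIO/IOB conversion

Three dialects are read (lean `token_TAG`, two-column with blank-line
sentence breaks, XML `<w iob=...>` tokens); extra columns such as
part-of-speech are read and discarded. Detokenization joins tokens with
single spaces — BIO carries no spacing information, and the toolkit
never claims to restore original spacing. Orphan `I` tags (no preceding
`B`/`I` of the same group) are repaired to `B` and logged, matching
conlleval-style tolerance: the variant problem is real and silent
failure would be worse than a logged repair. Writing BIO refuses nested
or same-extent spans and spans whose boundaries split a whitespace
token. BIOES/BILOU schemes are not supported. Both conversion
directions ship, the BIO→XML direction being the one the original
service only promised; XML→BIO is flagged as an extension of this
toolkit.

## League table

The store is an append-only line-delimited JSON file plus a
content-addressed archive directory (SHA-256 prefix of the serialized
corpus); immutability, not a database, is what an all-time record
requires. Every entry carries the standard column set (user, reference
file, assessment file, number of annotations, precision, recall,
F-score, alignment type, date) plus the mandatory free-text system
description and the archive path. `n_annotations` counts the *reference*
corpus: it describes the GSC, not the submission. Percent values are
stored at full precision and rendered at two decimals. Rendering sorts
by F descending; ties break by precision descending, then date
ascending, then the remaining fields, making the order total so that
insertion order can never influence the table. The tie-break below F is
a toolkit convention, not an inherited rule.

## Synthetic fixture generator

The generator emulates a GSC at configurable scale: documents of
pseudo-text sentences (filler words alternating with entity mentions of
1–3 tokens), typed spans over several semantic groups, optional nesting.
Each mention is preceded by the determiner "the", which is the handle
for boundary perturbation. The perturbed copy deletes each span with
probability `p_miss`, shifts one boundary of each survivor by one token
with probability `p_shift` (preferring to extend the start over the
preceding determiner, falling back to dropping the last token, and
never introducing a crossing overlap), and adds spurious spans on free
filler tokens at rate `p_spurious` per reference span. Spurious spans
never overlap reference spans, so the analytic expectations are clean:

- exact recall = (1 − p_miss)(1 − p_shift)
- exact precision = (1 − p_miss)(1 − p_shift) / ((1 − p_miss) + p_spurious)
- cos98 and nested recall = (1 − p_miss), because a determiner-extended
  span is recovered by the lexicon rule and a shrunken or extended span
  by containment.

The determiner-before-every-mention layout is the one deliberately
unrealistic regularity: it guarantees each shift has a lexicon word to
extend over, realizing TP(nested) − TP(exact) ≈ shift count exactly.
Real corpora have messier boundary errors (multi-token shifts,
non-lexicon extensions), real sentence text, and inter-annotator
ambiguity; passing the recovery tests shows the aligner and the counting
are correct under controlled perturbations, not that any particular
tagger achieves these scores on real data. Seeding is mandatory
(`numpy.random.default_rng`); the same configuration always reproduces
the same corpora bit for bit.

Recovery checks run on fixtures of roughly 1000 spans (25 documents × 10
sentences × 4 expected entities): the analytic band of ±3 points is
stated for fixtures of at least 400 spans, and at ~1000 spans the
binomial standard error of recall is about 1.4 points, keeping the check
comfortably inside the band. The brute-force matching oracle runs on
instances of up to 8 spans per side, where exhaustive assignment
enumeration is instant.

## Known limitations

- Sentence pairing requires (whitespace-normalized) text equality; a
  submission that rewrites sentence text will not align.
- cos98 is an interpretation of an under-specified historical measure;
  scores under that mode are comparable within this toolkit, not
  necessarily with the original service.
- Character offsets across reference and submission are assumed
  comparable because paired sentences have equal normalized text;
  pathological whitespace differences inside mentions can shift offsets
  between the two sides.
- One annotation layer per corpus file: simultaneous crossing
  alternative readings must be evaluated as separate submissions.
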