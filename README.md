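# nerleague

Entity-level evaluation of biomedical named entity recognition (NER)
output against gold standard corpora (GSCs), with a persistent,
F-sorted league table.

Benchmarking an NER system — a gene/protein, disease or chemical tagger —
against a GSC such as JNLPBA or BioCreative II is usually left to each
researcher, with ad-hoc scripts and no durable record. `nerleague`
packages that workflow as a reusable toolkit:

- **Corpus I/O** — a lossless reader/writer for an inline-annotation XML
  dialect (`<s id="1">the <e grp="PRGE">HZF-1</e> protein is</s>`) that,
  unlike BIO/IOB tagging, expresses nested and same-extent alternative
  annotations and marks boundaries without imposing a tokenization; plus
  converters for three BIO/IOB dialects (lean `token_TAG`, two-column
  CoNLL-style, and XML `<w iob="b">` token elements).
- **Alignment** — documents are paired by identifier, sentences by
  whitespace-normalized text, and entities by an exact
  maximum-cardinality one-to-one matching under a chosen mode.
- **Scoring** — micro-averaged precision P = 100·TP/(TP+FP), recall
  R = 100·TP/(TP+FN) and balanced F-measure F = 2PR/(P+R), with an
  error-type summary (boundary mismatch, group mismatch, missed,
  spurious).
- **League table** — an append-only store of submissions, each with a
  mandatory system description and an archived copy of the submitted
  corpus, rendered as an all-time table sorted by F-measure.

Three matching modes relax the boundary condition:

| mode   | a gold span g matches a submitted span s when |
|--------|-----------------------------------------------|
| exact  | boundaries coincide: (start, end) identical (the default; the standard in public challenges) |
| cos98  | the spans overlap and either their token-multiset cosine ≥ 0.98 or their symmetric token difference consists only of extension-lexicon words (determiners, "protein", "gene", ...) — symmetric |
| nested | one span fully contains the other, in either direction — asymmetric |

With group sensitivity on (the default), any match also requires equal
semantic groups.

## Worked example

`gold.xml` — two sentences, three gold spans (note the nested anatomy
span inside the disease span):

```xml
<corpus>
<document id="pmid1">
<s id="1">the <e grp="PRGE">HZF-1</e> protein is induced</s>
<s id="2"><e grp="DISO"><e grp="ANAT">left lung</e> cancer</e> treatment</s>
</document>
</corpus>
```

`run.xml` — a tagger's output: it extends the gene mention to
"HZF-1 protein", finds the disease but not the anatomy span:

```xml
<corpus>
<document id="pmid1">
<s id="1">the <e grp="PRGE">HZF-1 protein</e> is induced</s>
<s id="2"><e grp="DISO">left lung cancer</e> treatment</s>
</document>
</corpus>
```

```
$ nerleague evaluate --reference gold.xml --submission run.xml
mode:      exact
tp:        1
fp:        1
fn:        2
boundary_mismatch: 3
group_mismatch:    0
missed:            0
spurious:          0
precision: 50.00%
recall:    33.33%
f-measure: 40.00%
```

Under exact matching only the disease span survives: the extended gene
mention is a boundary mismatch (counted once as a false negative on the
gold side, once as a false positive on the submitted side) and the
nested anatomy span is unmatched. Relaxing the boundaries:

```
$ nerleague evaluate --reference gold.xml --submission run.xml --mode cos98
...
precision: 100.00%
recall:    66.67%
f-measure: 80.00%
```

cos98 now accepts "HZF-1" vs "HZF-1 protein" (the difference is the
generic head word "protein"); the anatomy span still has no same-group
counterpart. Recording the run and rendering the table:

```
$ nerleague submit --reference gold.xml --submission run.xml \
    --store store --user jdoe --description "dictionary tagger"
$ nerleague table --store store
User  Reference file  Assessment file  # of annotations  Precision  Recall  F-score  Alignment type  Date
jdoe  gold.xml        run.xml          3                 50.00%     33.33%  40.00%   Exact           2026-09-22
```

A submission without `--description` is rejected. `nerleague convert`
maps between the BIO dialects and the inline XML format, and
`nerleague fixture --seed N --out-dir D` emits a synthetic GSC together
with a perturbed copy and its analytic expected scores.

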