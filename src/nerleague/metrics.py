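"""Counts, error-type frequencies and precision/recall/F-measure.

Counting is micro-averaged: true positives, false positives and false
negatives are pooled across all sentences and documents before the
percentages are computed, consistent with challenge-style entity-level
evaluation.  Each unmatched span is classified into exactly one error
type:

- ``group_mismatch`` — an opposing span covers the same extent but
  carries a different semantic group;
- ``boundary_mismatch`` — an opposing span overlaps but with different
  boundaries;
- ``missed`` / ``spurious`` — no opposing span overlaps at all (false
  negative / false positive with no counterpart).

Zero denominators yield 0 by convention (conlleval behaviour); such an
evaluation is flagged as empty in the rendered report rather than
silently returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import MatchConfig, MatchResult, UnmatchedSpan, align_corpora
from .model import AnnotatedCorpus

__all__ = [
    "OutcomeCounts",
    "EvaluationResult",
    "ERROR_TYPES",
    "count_outcomes",
    "compute_metrics",
    "f_measure",
    "evaluate_corpora",
]

ERROR_TYPES = ("boundary_mismatch", "group_mismatch", "missed", "spurious")


@dataclass
class OutcomeCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    error_freq: dict[str, int] = field(
        default_factory=lambda: {e: 0 for e in ERROR_TYPES}
    )


@dataclass
class EvaluationResult:
    """Entity-level scores, in percent, with the counts behind them."""

    precision: float
    recall: float
    f_measure: float
    counts: OutcomeCounts
    mode: str

    @property
    def empty(self) -> bool:
        c = self.counts
        return c.tp + c.fp + c.fn == 0

    def render(self) -> str:
        lines = [
            f"mode:      {self.mode}",
            f"tp:        {self.counts.tp}",
            f"fp:        {self.counts.fp}",
            f"fn:        {self.counts.fn}",
        ]
        for error_type in ERROR_TYPES:
            lines.append(
                f"{error_type + ':':<19}{self.counts.error_freq[error_type]}"
            )
        lines += [
            f"precision: {self.precision:.2f}%",
            f"recall:    {self.recall:.2f}%",
            f"f-measure: {self.f_measure:.2f}%",
        ]
        if self.empty:
            lines.append("note: empty evaluation (no annotations on either side)")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "error_freq": dict(self.counts.error_freq),
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
        }


def _classify(unmatched: UnmatchedSpan, no_overlap_type: str) -> str:
    span = unmatched.span
    for other in unmatched.opposing:
        if span.same_extent(other) and span.group != other.group:
            return "group_mismatch"
    for other in unmatched.opposing:
        if span.overlaps(other):
            return "boundary_mismatch"
    return no_overlap_type


def count_outcomes(result: MatchResult) -> OutcomeCounts:
    """Fold a matching into TP/FP/FN counts and error-type frequencies.

    Conservation holds by construction: tp + fn equals the reference
    span count and tp + fp the submitted span count.
    """
    counts = OutcomeCounts(
        tp=len(result.pairs),
        fp=len(result.unmatched_submitted),
        fn=len(result.unmatched_reference),
    )
    for unmatched in result.unmatched_reference:
        counts.error_freq[_classify(unmatched, "missed")] += 1
    for unmatched in result.unmatched_submitted:
        counts.error_freq[_classify(unmatched, "spurious")] += 1
    return counts


def f_measure(precision: float, recall: float) -> float:
    """Balanced F-measure 2PR/(P+R) on percent inputs; 0 when P+R=0."""
    if not (0 <= precision <= 100 and 0 <= recall <= 100):
        raise ValueError("precision and recall must be percentages in [0, 100]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def compute_metrics(counts: OutcomeCounts, mode: str = "exact") -> EvaluationResult:
    """Precision, recall and F from pooled counts, as percentages.

    Full precision is retained internally; rendering rounds to two
    decimals.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    return EvaluationResult(
        precision=precision,
        recall=recall,
        f_measure=f_measure(precision, recall),
        counts=counts,
        mode=mode,
    )


def evaluate_corpora(
    reference: AnnotatedCorpus,
    submitted: AnnotatedCorpus,
    config: MatchConfig | None = None,
    **align_kwargs,
) -> EvaluationResult:
    """End-to-end evaluation of a submitted corpus against a GSC."""
    config = config or MatchConfig()
    result = align_corpora(reference, submitted, config, **align_kwargs)
    return compute_metrics(count_outcomes(result), config.mode)
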