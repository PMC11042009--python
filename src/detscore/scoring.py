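"""Potential-determinant scoring of terms across a two-corpus contrast.

For every term t that occurs anywhere in the positive corpus Cp, three
quantities are computed against the negative corpus Cn:

``b(t)``
    proportional occurrence, n(t, Cp) / (n(t, Cp) + n(t, Cn)) — the
    fraction of the term's total occurrences (raw multiset counts, both
    corpora pooled) that fall in Cp;

``dist(t)``
    document-distribution fraction, DCp(t) / DCp — the fraction of Cp
    documents containing the term at least once (multiplicity within a
    document is deliberately ignored, so one document mentioning a term
    fifty times contributes exactly one containing document);

``a(t)``
    the determinant score, the arithmetic mean (b(t) + dist(t)) / 2.

Scores lie in [0, 1]; a(t) = 1 exactly when the term never occurs in Cn
and appears in every Cp document.  High b with low dist flags a term whose
excess in Cp is attributable to a single enthusiastic document; high dist
with b near 1/2 flags a term that is ubiquitous but not contrastive.  The
mean rewards terms strong on both axes.

Only terms of the test set B — the union of normalized term sets over Cp
documents — are scored; a term confined to Cn is by construction not a
candidate determinant of positive results.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .normalize import NormalizedDocument

__all__ = [
    "TermStatistics",
    "build_test_set",
    "term_counts",
    "proportional_occurrence",
    "distribution_fraction",
    "score_term",
    "score_all",
]


@dataclass(frozen=True)
class TermStatistics:
    """All per-term statistics, with exact integer counts retained.

    The float fields are derived ratios; the integer numerators and
    denominators are kept so downstream consumers can re-derive them at
    full precision.
    """

    term: str
    n_pos: int            # n(t, Cp): raw occurrences in the positive corpus
    n_total: int          # n(t, Cp, Cn): raw occurrences pooled over both
    doc_count_pos: int    # DCp(t): positive documents containing the term
    n_docs_pos: int       # DCp: number of positive documents

    def __post_init__(self) -> None:
        if not (0 <= self.n_pos <= self.n_total):
            raise ValueError(f"{self.term!r}: need 0 <= n_pos <= n_total")
        if self.n_total == 0:
            raise ValueError(f"{self.term!r}: n_total must be >= 1")
        if not (0 <= self.doc_count_pos <= self.n_docs_pos):
            raise ValueError(f"{self.term!r}: need 0 <= doc_count_pos <= n_docs_pos")
        if self.n_docs_pos == 0:
            raise ValueError(f"{self.term!r}: positive corpus has no documents")

    @property
    def b(self) -> float:
        """Proportional occurrence b(t) in [0, 1]."""
        return self.n_pos / self.n_total

    @property
    def dist_fraction(self) -> float:
        """Document-distribution fraction DCp(t)/DCp in [0, 1]."""
        return self.doc_count_pos / self.n_docs_pos

    @property
    def score(self) -> float:
        """The determinant score a(t) = (b + dist_fraction) / 2."""
        return (self.b + self.dist_fraction) / 2.0


def build_test_set(pos_docs: Sequence[NormalizedDocument]) -> frozenset[str]:
    """The test set B: every distinct normalized term occurring in Cp.

    An exact set union over document term sets; no frequency threshold is
    applied, so hapax terms are scored too.
    """
    if not pos_docs:
        raise ValueError("cannot build a test set from an empty corpus")
    terms: set[str] = set()
    for doc in pos_docs:
        terms |= doc.term_set
    return frozenset(terms)


def term_counts(docs: Iterable[NormalizedDocument]) -> Counter[str]:
    """Pooled raw occurrence counts over the documents' token multisets."""
    counts: Counter[str] = Counter()
    for doc in docs:
        counts.update(doc.tokens)
    return counts


def proportional_occurrence(
    term: str,
    pos_counts: Mapping[str, int],
    neg_counts: Mapping[str, int],
) -> float:
    """b(t): the fraction of a term's pooled occurrences that fall in Cp.

    Undefined (raises) for a term absent from both corpora; this is never
    silently reported as zero because b = 0 means "occurs, only in Cn",
    which is a different statement.
    """
    n_pos = pos_counts.get(term, 0)
    n_total = n_pos + neg_counts.get(term, 0)
    if n_total == 0:
        raise ValueError(f"term {term!r} occurs in neither corpus; b(t) undefined")
    return n_pos / n_total


def distribution_fraction(term: str, pos_docs: Sequence[NormalizedDocument]) -> float:
    """DCp(t)/DCp: fraction of positive documents containing the term."""
    if not pos_docs:
        raise ValueError("positive corpus is empty; distribution undefined")
    containing = sum(1 for doc in pos_docs if term in doc.term_set)
    return containing / len(pos_docs)


def score_term(b: float, dist_fraction: float) -> float:
    """a(t): arithmetic mean of proportional occurrence and distribution."""
    if not (0.0 <= b <= 1.0):
        raise ValueError(f"b out of [0, 1]: {b}")
    if not (0.0 <= dist_fraction <= 1.0):
        raise ValueError(f"dist_fraction out of [0, 1]: {dist_fraction}")
    return (b + dist_fraction) / 2.0


def score_all(
    pos_docs: Sequence[NormalizedDocument],
    neg_docs: Sequence[NormalizedDocument],
) -> list[TermStatistics]:
    """Score every term of the test set B against the negative corpus.

    Returns one :class:`TermStatistics` per term of B, sorted by score
    descending with the term string as tie-break.  Terms occurring only in
    the negative corpus are not scored.
    """
    if not pos_docs:
        raise ValueError("positive corpus is empty")
    if not neg_docs:
        raise ValueError("negative corpus is empty")
    pos_counts = term_counts(pos_docs)
    neg_counts = term_counts(neg_docs)
    n_docs_pos = len(pos_docs)
    doc_counts: Counter[str] = Counter()
    for doc in pos_docs:
        doc_counts.update(doc.term_set)

    stats = [
        TermStatistics(
            term=term,
            n_pos=pos_counts[term],
            n_total=pos_counts[term] + neg_counts.get(term, 0),
            doc_count_pos=doc_counts[term],
            n_docs_pos=n_docs_pos,
        )
        for term in build_test_set(pos_docs)
    ]
    stats.sort(key=lambda s: (-s.score, s.term))
    return stats
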