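"""Classical TF-IDF and the mean-rank comparison used as a baseline.

TF-IDF scores a term t in a document d as

    tfidf(t, d) = f(t, d) * log(|D| / DF(t))

with f the raw in-document frequency, |D| the corpus size and DF(t) the
number of documents containing the term.  The natural logarithm is used;
since a change of log base multiplies every score by the same positive
constant, the *rankings* this module reports are base-invariant.

The baseline procedure ranks, for each document, all terms present in it
(rank 1 = most prominent) and then averages a term's rank over the
documents that contain it, separately in each corpus.  A term contained
in no document of a corpus has no mean rank there (``None``, serialized
"NA").  Comparing a term's mean rank between the positive and negative
corpus shows how (un)prominent conventional topic salience considers a
term that the contrastive score flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .normalize import NormalizedDocument

__all__ = [
    "tfidf_score",
    "TfidfRanking",
    "rank_document_terms",
    "mean_rank",
    "MeanRankResult",
    "mean_rank_table",
]


def tfidf_score(f: int, n_docs: int, df: int, *, base: float | None = None) -> float:
    """TF-IDF of a term given its raw frequency and document frequency.

    ``base=None`` means the natural logarithm.  A term with f = 0 scores 0
    regardless of df; a term claimed present (f >= 1) with df = 0 is an
    inconsistency and raises.
    """
    if n_docs < 1:
        raise ValueError("corpus must contain at least one document")
    if f < 0 or df < 0 or df > n_docs:
        raise ValueError(f"inconsistent counts: f={f}, df={df}, n_docs={n_docs}")
    if f == 0:
        return 0.0
    if df == 0:
        raise ValueError("term has occurrences (f >= 1) but document frequency 0")
    idf = math.log(n_docs / df) if base is None else math.log(n_docs / df, base)
    return f * idf


@dataclass(frozen=True)
class TfidfRanking:
    """Per-document ranking of the document's own terms.

    ``ranked_terms`` holds (term, tfidf_score, rank) with rank 1 the most
    prominent; ranks are the dense ordinal positions 1..k over the
    document's distinct terms and scores are non-increasing with rank.
    """

    doc_id: str
    ranked_terms: tuple[tuple[str, float, int], ...]

    def rank_of(self, term: str) -> int | None:
        for t, _, r in self.ranked_terms:
            if t == term:
                return r
        return None


def rank_document_terms(
    doc: NormalizedDocument,
    corpus_docs: Sequence[NormalizedDocument],
    *,
    base: float | None = None,
) -> TfidfRanking:
    """Score and rank every distinct term of ``doc`` within its corpus.

    Document frequencies are established against ``corpus_docs`` (which
    must include ``doc`` itself).  Ties on score are broken by higher raw
    frequency first, then alphabetically, so rankings are deterministic.
    An empty document yields an empty ranking.
    """
    if not any(d.doc_id == doc.doc_id for d in corpus_docs):
        raise ValueError(f"document {doc.doc_id!r} is not part of the corpus given")
    n_docs = len(corpus_docs)
    freqs: dict[str, int] = {}
    for tok in doc.tokens:
        freqs[tok] = freqs.get(tok, 0) + 1
    scored = []
    for term, f in freqs.items():
        df = sum(1 for d in corpus_docs if term in d.term_set)
        scored.append((term, tfidf_score(f, n_docs, df, base=base), f))
    scored.sort(key=lambda x: (-x[1], -x[2], x[0]))
    ranked = tuple((term, s, i + 1) for i, (term, s, _) in enumerate(scored))
    return TfidfRanking(doc_id=doc.doc_id, ranked_terms=ranked)


def mean_rank(
    term: str,
    corpus_docs: Sequence[NormalizedDocument],
    *,
    base: float | None = None,
) -> float | None:
    """Mean TF-IDF rank of a term over the documents containing it.

    Documents not containing the term contribute nothing (no worst-rank
    imputation); if no document contains it the mean rank is undefined and
    None is returned.
    """
    if not corpus_docs:
        raise ValueError("corpus is empty")
    ranks = []
    for doc in corpus_docs:
        if term in doc.term_set:
            rank = rank_document_terms(doc, corpus_docs, base=base).rank_of(term)
            ranks.append(rank)
    if not ranks:
        return None
    return sum(ranks) / len(ranks)


@dataclass(frozen=True)
class MeanRankResult:
    """A term's mean TF-IDF rank in each corpus (None = absent there)."""

    term: str
    mean_rank_pos: float | None
    mean_rank_neg: float | None


def mean_rank_table(
    terms: Sequence[str],
    pos_docs: Sequence[NormalizedDocument],
    neg_docs: Sequence[NormalizedDocument],
) -> list[MeanRankResult]:
    """Mean ranks for a list of terms, computed per corpus independently.

    Document frequencies for the positive corpus come from the positive
    corpus only, and likewise for the negative corpus.
    """
    if not terms:
        raise ValueError("no terms requested")
    # rank each document once, then look ranks up per term
    pos_rankings = [rank_document_terms(d, pos_docs) for d in pos_docs]
    neg_rankings = [rank_document_terms(d, neg_docs) for d in neg_docs]

    def _mean(term: str, rankings: list[TfidfRanking]) -> float | None:
        ranks = [r.rank_of(term) for r in rankings]
        ranks = [r for r in ranks if r is not None]
        return sum(ranks) / len(ranks) if ranks else None

    return [
        MeanRankResult(
            term=t,
            mean_rank_pos=_mean(t, pos_rankings),
            mean_rank_neg=_mean(t, neg_rankings),
        )
        for t in terms
    ]
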