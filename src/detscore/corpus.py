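"""Reading document collections and writing result tables.

A *corpus* here is a labelled, ordered collection of plain-text documents:
either the "positive" collection (reports of significant beneficial results
on the research question) or the "negative" collection (insignificant or
negative results on the same question).  The contrastive scoring machinery
always operates on a :class:`CorpusPair` of the two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CorpusLabel",
    "Document",
    "Corpus",
    "CorpusPair",
    "load_corpus",
    "load_corpus_pair",
    "write_results",
    "read_results",
]


class CorpusLabel(str, Enum):
    """Which side of the contrast a corpus sits on."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class Document:
    """One raw text unit (one file on disk).

    ``doc_id`` must be non-empty and unique within its corpus; ``text`` is
    the verbatim character content of the file.
    """

    doc_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class Corpus:
    """A labelled, ordered collection of documents."""

    label: CorpusLabel
    documents: tuple[Document, ...]

    def __post_init__(self) -> None:
        if not self.documents:
            raise ValueError(f"corpus {self.label.value!r} has no documents")
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate doc_ids in corpus: {dupes}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]


@dataclass(frozen=True)
class CorpusPair:
    """The positive and negative corpus analysed together.

    Document ids must be disjoint across the pair; colliding ids are
    namespaced by the corpus label at construction time via
    :func:`load_corpus_pair`.
    """

    positive: Corpus
    negative: Corpus

    def __post_init__(self) -> None:
        if self.positive.label is not CorpusLabel.POSITIVE:
            raise ValueError("positive corpus carries a non-positive label")
        if self.negative.label is not CorpusLabel.NEGATIVE:
            raise ValueError("negative corpus carries a non-negative label")
        overlap = set(self.positive.doc_ids) & set(self.negative.doc_ids)
        if overlap:
            raise ValueError(
                f"doc_ids shared between corpora: {sorted(overlap)}; "
                "namespace them (e.g. via load_corpus_pair) first"
            )


def load_corpus(
    directory: str | Path,
    label: CorpusLabel | str,
    *,
    allow_empty_files: bool = False,
    pattern: str = "*.txt",
) -> Corpus:
    """Load every text file in ``directory`` as one document each.

    Files are read as UTF-8 and taken in lexicographic filename order so
    repeated runs see documents in the same order (the scoring statistics
    are order-invariant regardless; determinism just keeps logs and output
    reproducible byte for byte).  The document id is the filename stem.

    Parameters
    ----------
    directory:
        Directory containing one ``.txt`` file per document.
    label:
        ``"positive"`` or ``"negative"``.
    allow_empty_files:
        By default a zero-length (or whitespace-only) file is an error,
        since it almost always indicates a broken export; set True to admit
        it as an empty document.

    Raises
    ------
    FileNotFoundError
        If the directory does not exist or contains no matching files.
    ValueError
        On empty files (unless allowed) or duplicate stems.
    UnicodeDecodeError
        On undecodable bytes; the offending filename is attached.
    """
    label = CorpusLabel(label)
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"corpus directory not found: {directory}")
    paths = sorted(directory.glob(pattern), key=lambda p: p.name)
    if not paths:
        raise FileNotFoundError(f"no documents found in {directory} (pattern {pattern!r})")
    docs = []
    for path in paths:
        try:
            text = path.read_text(encoding="utf-8")
        except UnicodeDecodeError as err:
            raise UnicodeDecodeError(
                err.encoding, err.object, err.start, err.end,
                f"{err.reason} (while reading {path})",
            ) from None
        if not text.strip() and not allow_empty_files:
            raise ValueError(
                f"document file is empty: {path} (pass allow_empty_files=True to accept)"
            )
        docs.append(Document(doc_id=path.stem, text=text))
    return Corpus(label=label, documents=tuple(docs))


def load_corpus_pair(
    pos_dir: str | Path,
    neg_dir: str | Path,
    *,
    allow_empty_files: bool = False,
) -> CorpusPair:
    """Load the positive and negative corpora, namespacing colliding ids.

    If a document id occurs in both directories the ids of *both* documents
    are prefixed with their corpus label (``positive:stem`` /
    ``negative:stem``) so the pair-wide uniqueness invariant holds.
    """
    pos = load_corpus(pos_dir, CorpusLabel.POSITIVE, allow_empty_files=allow_empty_files)
    neg = load_corpus(neg_dir, CorpusLabel.NEGATIVE, allow_empty_files=allow_empty_files)
    overlap = set(pos.doc_ids) & set(neg.doc_ids)
    if overlap:
        def _namespace(corpus: Corpus) -> Corpus:
            docs = tuple(
                Document(f"{corpus.label.value}:{d.doc_id}", d.text)
                if d.doc_id in overlap else d
                for d in corpus.documents
            )
            return Corpus(label=corpus.label, documents=docs)
        pos, neg = _namespace(pos), _namespace(neg)
    return CorpusPair(positive=pos, negative=neg)


#: Column order of the result table, shared by the TSV and JSON writers.
RESULT_COLUMNS = (
    "term", "n_pos", "n_total", "b",
    "doc_count_pos", "dist_fraction", "score", "selected",
)

_FLOAT_COLUMNS = ("b", "dist_fraction", "score")


def _results_frame(stats: Iterable, selected_terms: set[str]) -> pd.DataFrame:
    rows = [
        {
            "term": s.term,
            "n_pos": s.n_pos,
            "n_total": s.n_total,
            "b": s.b,
            "doc_count_pos": s.doc_count_pos,
            "dist_fraction": s.dist_fraction,
            "score": s.score,
            "selected": s.term in selected_terms,
        }
        for s in stats
    ]
    frame = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    # stable contract: score descending, term ascending breaks ties
    return frame.sort_values(
        ["score", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def write_results(
    stats: Sequence,
    path: str | Path,
    fmt: str = "tsv",
    *,
    selected_terms: Iterable[str] = (),
    allow_empty: bool = False,
) -> None:
    """Write per-term statistics as a TSV or JSON table.

    Rows are sorted by score descending with the term string as an
    alphabetic tie-break, and float columns are serialised at four decimal
    places so repeated runs diff cleanly.

    Parameters
    ----------
    stats:
        ``TermStatistics`` records (anything with the result fields works).
    selected_terms:
        Terms that survived candidate selection; flagged in the
        ``selected`` column.
    """
    if not stats and not allow_empty:
        raise ValueError("refusing to write an empty result table (allow_empty=False)")
    frame = _results_frame(stats, set(selected_terms))
    path = Path(path)
    if fmt == "tsv":
        out = frame.copy()
        for col in _FLOAT_COLUMNS:
            out[col] = out[col].map(lambda v: f"{v:.4f}")
        out["selected"] = out["selected"].map(lambda v: "true" if v else "false")
        out.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        records = frame.to_dict(orient="records")
        for rec in records:
            for col in _FLOAT_COLUMNS:
                rec[col] = round(float(rec[col]), 4)
        path.write_text(json.dumps(records, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown result format: {fmt!r} (expected 'tsv' or 'json')")


def read_results(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a table written by :func:`write_results` back into a DataFrame."""
    path = Path(path)
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype={"term": str})
        frame["selected"] = frame["selected"].map({"true": True, "false": False, True: True, False: False})
    elif fmt == "json":
        frame = pd.DataFrame(json.loads(path.read_text(encoding="utf-8")), columns=list(RESULT_COLUMNS))
    else:
        raise ValueError(f"unknown result format: {fmt!r}")
    return frame
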