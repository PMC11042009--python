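"""Text normalization: raw document -> multiset of normalized terms.

Every document passes through the same four-step pipeline before any
counting happens: tokenize, lowercase, strip punctuation, remove
stopwords, then lemmatize.  The candidate lexicon is pushed through the
identical transformation (:func:`normalize_term`) so corpus terms and
lexicon entries meet on the same normalized forms.

Hyphens internal to a token are preserved by default so compound names
like "omega-3" survive as a single countable term.  Standalone numerals
are kept unless ``strip_digits`` is set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable

from .corpus import Corpus, CorpusPair, Document
from .lemmatize import identity_lemmatize, lemmatize

__all__ = [
    "PreprocessConfig",
    "NormalizedDocument",
    "load_stopwords",
    "default_stopwords",
    "normalize_document",
    "normalize_corpus",
    "normalize_pair",
    "normalize_term",
    "raw_word_count",
]

_LEMMATIZERS: dict[str, Callable[[str], str]] = {
    "dictionary": lemmatize,
    "identity": identity_lemmatize,
}


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stopword file: one lowercase token per line, '#' comments."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


def default_stopwords() -> frozenset[str]:
    """The frozen English stopword list shipped with the package."""
    ref = resources.files("detscore").joinpath("data/stopwords.txt")
    words = set()
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


@dataclass(frozen=True)
class PreprocessConfig:
    """Normalization settings, fixed for the whole run.

    Attributes
    ----------
    stopwords:
        Lowercase function words removed before lemmatization.
    lemmatizer_mode:
        ``"dictionary"`` (rule/exception-table lemmatizer) or
        ``"identity"`` (surface forms kept as-is).
    keep_internal_hyphens:
        Keep hyphens inside tokens ("omega-3"); edge hyphens always go.
    strip_digits:
        Drop tokens that are purely numeric.
    """

    stopwords: frozenset[str] = field(default_factory=default_stopwords)
    lemmatizer_mode: str = "dictionary"
    keep_internal_hyphens: bool = True
    strip_digits: bool = False

    #: Human-readable description of the token pattern, recorded in manifests.
    @property
    def token_pattern(self) -> str:
        hyph = "with internal hyphens kept" if self.keep_internal_hyphens else "hyphens split"
        return f"maximal runs of [a-z0-9] {hyph}, lowercased, punctuation stripped"

    def __post_init__(self) -> None:
        if self.lemmatizer_mode not in _LEMMATIZERS:
            raise ValueError(
                f"unknown lemmatizer_mode {self.lemmatizer_mode!r}; "
                f"expected one of {sorted(_LEMMATIZERS)}"
            )
        for w in self.stopwords:
            if w != w.lower():
                raise ValueError(f"stopword not lowercase: {w!r}")

    @property
    def lemmatizer(self) -> Callable[[str], str]:
        return _LEMMATIZERS[self.lemmatizer_mode]

    def to_dict(self) -> dict:
        return {
            "lemmatizer_mode": self.lemmatizer_mode,
            "keep_internal_hyphens": self.keep_internal_hyphens,
            "strip_digits": self.strip_digits,
            "n_stopwords": len(self.stopwords),
            "token_pattern": self.token_pattern,
        }


@dataclass(frozen=True)
class NormalizedDocument:
    """A document reduced to its multiset of normalized terms.

    ``tokens`` preserves multiplicity (it is the token sequence after
    normalization); ``raw_word_count`` is the whitespace-token count of the
    untouched text, recorded before any filtering so corpus word-count
    reporting matches a plain word count of the files.
    """

    doc_id: str
    tokens: tuple[str, ...]
    raw_word_count: int

    @property
    def term_set(self) -> frozenset[str]:
        return frozenset(self.tokens)


_TOKEN_HYPH = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")
_TOKEN_PLAIN = re.compile(r"[a-z0-9]+")


def _tokenize(text: str, config: PreprocessConfig) -> list[str]:
    pattern = _TOKEN_HYPH if config.keep_internal_hyphens else _TOKEN_PLAIN
    return pattern.findall(text.lower())


def raw_word_count(text: str) -> int:
    """Whitespace-token count of raw text (the 'combined length in words')."""
    return len(text.split())


def _normalize_tokens(text: str, config: PreprocessConfig) -> list[str]:
    lem = config.lemmatizer
    out = []
    for tok in _tokenize(text, config):
        if tok in config.stopwords:
            continue
        if config.strip_digits and tok.replace("-", "").isdigit():
            continue
        tok = lem(tok)
        # a lemma can itself be a function word ("cans" -> "can"); filter
        # again so normalization is idempotent on its own output
        if tok and tok not in config.stopwords:
            out.append(tok)
    return out


def normalize_document(doc: Document, config: PreprocessConfig | None = None) -> NormalizedDocument:
    """Run the full normalization pipeline on one document.

    The pipeline depends only on the document text and the config — no
    corpus-level statistics leak in — so documents can be normalized in
    any order or in parallel.
    """
    config = config or PreprocessConfig()
    return NormalizedDocument(
        doc_id=doc.doc_id,
        tokens=tuple(_normalize_tokens(doc.text, config)),
        raw_word_count=raw_word_count(doc.text),
    )


def normalize_corpus(corpus: Corpus, config: PreprocessConfig | None = None) -> list[NormalizedDocument]:
    config = config or PreprocessConfig()
    return [normalize_document(d, config) for d in corpus]


def normalize_pair(
    pair: CorpusPair, config: PreprocessConfig | None = None
) -> tuple[list[NormalizedDocument], list[NormalizedDocument]]:
    """Normalize both corpora of a pair with one shared config."""
    config = config or PreprocessConfig()
    return normalize_corpus(pair.positive, config), normalize_corpus(pair.negative, config)


def normalize_term(term: str, config: PreprocessConfig | None = None) -> list[str]:
    """Normalize a standalone term exactly as document text is normalized.

    May yield zero tokens (the term is a stopword or pure punctuation),
    one token, or several (a multiword compound name).
    """
    if not term:
        raise ValueError("term must be non-empty")
    config = config or PreprocessConfig()
    return _normalize_tokens(term, config)
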