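"""Shared fixtures and tiny builders for the test suite."""

from __future__ import annotations

import pytest

from detscore.corpus import Corpus, CorpusLabel, CorpusPair, Document
from detscore.normalize import NormalizedDocument, PreprocessConfig


def ndoc(doc_id: str, tokens: str | list[str]) -> NormalizedDocument:
    """Build a NormalizedDocument straight from a token string."""
    toks = tokens.split() if isinstance(tokens, str) else list(tokens)
    return NormalizedDocument(doc_id=doc_id, tokens=tuple(toks), raw_word_count=len(toks))


def make_pair(pos_texts: dict[str, str], neg_texts: dict[str, str]) -> CorpusPair:
    """Build a CorpusPair from {doc_id: raw text} mappings."""
    pos = Corpus(
        label=CorpusLabel.POSITIVE,
        documents=tuple(Document(k, v) for k, v in pos_texts.items()),
    )
    neg = Corpus(
        label=CorpusLabel.NEGATIVE,
        documents=tuple(Document(k, v) for k, v in neg_texts.items()),
    )
    return CorpusPair(positive=pos, negative=neg)


@pytest.fixture
def identity_config() -> PreprocessConfig:
    """Surface-form pipeline: no stopwords, no lemmatization."""
    return PreprocessConfig(stopwords=frozenset(), lemmatizer_mode="identity")


@pytest.fixture
def corpus_dir(tmp_path):
    """Factory writing {name: text} as a directory of .txt files."""
    counter = {"n": 0}

    def _write(files: dict[str, str]):
        counter["n"] += 1
        d = tmp_path / f"corpus{counter['n']}"
        d.mkdir()
        for name, text in files.items():
            (d / f"{name}.txt").write_text(text, encoding="utf-8")
        return d

    return _write
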