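"""Candidate selection: lexicon filtering and percentile thresholding.

Scoring alone ranks every term in the positive corpus; selection narrows
that ranking to candidate determinants with three composable filters:

1. contrast filter — proportional occurrence b(t) strictly above 0.5, so
   every candidate already occurs more in the positive corpus;
2. score filter — a(t) strictly above a percentile (default the 75th) of
   the score distribution over the *whole* test set B, computed before any
   other filtering;
3. lexicon filter — membership in the user-supplied candidate list q
   (e.g. a list of nutritional compound names), restricting results to a
   studyable category of interest.

The filters are pure predicates, so their application order is
irrelevant, and tightening either threshold can only shrink the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .normalize import PreprocessConfig, normalize_term
from .scoring import TermStatistics

__all__ = [
    "Lexicon",
    "SelectionConfig",
    "load_lexicon",
    "percentile_threshold",
    "select_determinants",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Lexicon:
    """The normalized candidate-term list q.

    Entries are single normalized tokens.  Source lines that normalized to
    more than one token (multiword compound names) cannot match the
    unigram unit of analysis and are recorded in ``dropped_multiword``
    rather than silently discarded.
    """

    entries: frozenset[str]
    dropped_multiword: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("lexicon has no single-token entries")
        bad = [e for e in self.entries if not e or e != e.lower() or " " in e]
        if bad:
            raise ValueError(f"non-normalized lexicon entries: {bad[:5]}")

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def load_lexicon(path: str | Path, config: PreprocessConfig | None = None) -> Lexicon:
    """Load and normalize a candidate lexicon file.

    One raw term per line, UTF-8, '#' comment lines allowed.  Each line is
    normalized exactly as document text is; single-token results become
    entries (set semantics, duplicates collapse), multi-token results are
    dropped with a warning, and lines that normalize to nothing (pure
    stopwords or punctuation) are ignored.
    """
    config = config or PreprocessConfig()
    path = Path(path)
    lines = [
        ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"lexicon file is empty: {path}")
    entries: set[str] = set()
    dropped: list[str] = []
    for raw in lines:
        tokens = normalize_term(raw, config)
        if len(tokens) == 1:
            entries.add(tokens[0])
        elif len(tokens) > 1:
            dropped.append(raw)
    if dropped:
        logger.warning(
            "%d multiword lexicon entries dropped (unigram analysis): %s%s",
            len(dropped), ", ".join(dropped[:5]), "..." if len(dropped) > 5 else "",
        )
    if not entries:
        raise ValueError(f"no single-token entries remained after normalizing {path}")
    return Lexicon(entries=frozenset(entries), dropped_multiword=tuple(dropped))


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for candidate selection (defaults follow the method)."""

    percentile: float = 75.0
    min_proportion: float = 0.5
    require_lexicon: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile < 100.0):
            raise ValueError(f"percentile must be in (0, 100): {self.percentile}")
        if not (0.0 <= self.min_proportion <= 1.0):
            raise ValueError(f"min_proportion must be in [0, 1]: {self.min_proportion}")

    def to_dict(self) -> dict:
        return {
            "percentile": self.percentile,
            "min_proportion": self.min_proportion,
            "require_lexicon": self.require_lexicon,
        }


def percentile_threshold(scores: Sequence[float], percentile: float = 75.0) -> float:
    """Linear-interpolation percentile of the score distribution.

    Computed over ALL scores of the test set B, before the contrast or
    lexicon filters touch anything, so the threshold reflects the full
    score distribution.
    """
    if len(scores) == 0:
        raise ValueError("cannot take a percentile of zero scores")
    return float(np.percentile(np.asarray(scores, dtype=float), percentile))


def select_determinants(
    stats: Sequence[TermStatistics],
    lexicon: Lexicon | None,
    config: SelectionConfig | None = None,
) -> list[TermStatistics]:
    """Apply the three selection filters and rank the survivors.

    Both numeric filters are strict inequalities ("above 0.5", "above the
    percentile").  ``lexicon`` may be None only when
    ``config.require_lexicon`` is False.  Survivors are returned sorted by
    score descending, term ascending on ties.  An empty result is valid
    (and logged prominently): it means no candidate in the category of
    interest cleared the contrast and score bars.
    """
    config = config or SelectionConfig()
    if config.require_lexicon and lexicon is None:
        raise ValueError("require_lexicon is set but no lexicon was given")
    if not stats:
        raise ValueError("no term statistics to select from")
    threshold = percentile_threshold([s.score for s in stats], config.percentile)
    selected = [
        s for s in stats
        if s.b > config.min_proportion
        and s.score > threshold
        and (lexicon is None or s.term in lexicon)
    ]
    selected.sort(key=lambda s: (-s.score, s.term))
    if not selected:
        logger.warning(
            "selection is EMPTY: no term passed b > %.3g, score > %.4g and the lexicon filter",
            config.min_proportion, threshold,
        )
    return selected
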