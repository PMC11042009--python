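"""End-to-end orchestration: load -> normalize -> score -> select -> report.

The run manifest records everything needed to reproduce a run given the
input files: the preprocessing and selection configuration, raw corpus
word counts, the test-set size, the percentile threshold actually used,
and survivor counts at each filter stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Sequence

from . import __version__
from .corpus import CorpusPair
from .normalize import NormalizedDocument, PreprocessConfig, normalize_pair
from .scoring import TermStatistics, score_all
from .selection import Lexicon, SelectionConfig, percentile_threshold, select_determinants

__all__ = ["ScoringRun", "run_scoring"]

logger = logging.getLogger(__name__)

#: Warn when corpus lengths differ by more than this relative gap, since the
#: raw-count statistics carry no document-length normalization.
LENGTH_IMBALANCE_WARN = 0.25


@dataclass(frozen=True)
class ScoringRun:
    """Everything produced by one scoring run."""

    stats: list[TermStatistics]
    selected: list[TermStatistics]
    threshold: float
    manifest: dict

    @property
    def selected_terms(self) -> list[str]:
        return [s.term for s in self.selected]


def _word_count(docs: Sequence[NormalizedDocument]) -> int:
    return sum(d.raw_word_count for d in docs)


def run_scoring(
    pair: CorpusPair,
    lexicon: Lexicon | None,
    preprocess: PreprocessConfig | None = None,
    selection: SelectionConfig | None = None,
) -> ScoringRun:
    """Score every positive-corpus term and select candidate determinants."""
    preprocess = preprocess or PreprocessConfig()
    selection = selection or SelectionConfig()

    pos_docs, neg_docs = normalize_pair(pair, preprocess)
    wc_pos, wc_neg = _word_count(pos_docs), _word_count(neg_docs)
    logger.info("corpus word counts: positive=%d, negative=%d", wc_pos, wc_neg)
    if min(wc_pos, wc_neg) and abs(wc_pos - wc_neg) / max(wc_pos, wc_neg) > LENGTH_IMBALANCE_WARN:
        logger.warning(
            "corpus lengths differ by more than %d%% (%d vs %d words); raw-count "
            "proportions carry no length normalization, interpret b(t) with care",
            int(LENGTH_IMBALANCE_WARN * 100), wc_pos, wc_neg,
        )

    stats = score_all(pos_docs, neg_docs)
    logger.info("test set size |B| = %d unique terms", len(stats))

    threshold = percentile_threshold([s.score for s in stats], selection.percentile)
    logger.info(
        "score threshold: %.4f (%.6gth percentile, linear interpolation)",
        threshold, selection.percentile,
    )
    n_pass_b = sum(1 for s in stats if s.b > selection.min_proportion)
    n_pass_score = sum(1 for s in stats if s.score > threshold)
    selected = select_determinants(stats, lexicon, selection)
    logger.info(
        "filter survivors: b > %.3g: %d; score > threshold: %d; selected (all filters): %d",
        selection.min_proportion, n_pass_b, n_pass_score, len(selected),
    )

    manifest = {
        "tool": "detscore",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "preprocess": preprocess.to_dict(),
        "selection": selection.to_dict(),
        "lexicon_size": len(lexicon) if lexicon is not None else None,
        "n_docs_pos": len(pos_docs),
        "n_docs_neg": len(neg_docs),
        "word_count_pos": wc_pos,
        "word_count_neg": wc_neg,
        "test_set_size": len(stats),
        "score_threshold": threshold,
        "survivors_b_filter": n_pass_b,
        "survivors_score_filter": n_pass_score,
        "n_selected": len(selected),
    }
    return ScoringRun(stats=stats, selected=selected, threshold=threshold, manifest=manifest)
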