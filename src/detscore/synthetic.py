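"""Synthetic two-corpus generation with planted determinant terms.

The generator emulates the study setting end to end: a shared background
vocabulary with Zipf-distributed token frequencies stands in for ordinary
scientific prose, and *planted* terms with controlled proportional
occurrence (target b) and positive-document distribution (target dist)
stand in for genuine determinants.  The canonical scoring scenarios are
directly expressible:

- strong distribution and strong proportional occurrence (the ideal,
  high-scoring case),
- high proportional occurrence concentrated in a single positive document
  (score tempered by weak distribution),
- balanced occurrence with consistent positive distribution (score
  tempered by a near-1/2 contrast).

Plants are placed by substituting background tokens *after* background
sampling, so document lengths are exactly what the length model drew.
Because integer occurrence counts cannot always hit a fractional target
exactly, the generator returns the *realized* ground truth alongside the
corpora; tests compare recovered statistics against realized, not target,
values.  The default corpus shape mirrors a small systematic-review
setting: nine positive and seven negative documents of a few thousand
words each over a shared vocabulary of several thousand types.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import Corpus, CorpusLabel, CorpusPair, Document
from .normalize import PreprocessConfig, normalize_term
from .scoring import TermStatistics

__all__ = [
    "PlantedTerm",
    "SyntheticSpec",
    "GroundTruth",
    "generate_pair",
    "write_pair",
    "recovery_report",
    "demo_spec",
]


@dataclass(frozen=True)
class PlantedTerm:
    """A signal term to embed with controlled contrast statistics.

    ``target_b`` is the desired proportional occurrence in the positive
    corpus; ``target_dist`` the desired fraction of positive documents
    containing the term; ``total_occurrences`` the pooled count to split
    between the corpora.
    """

    term: str
    target_b: float
    target_dist: float
    total_occurrences: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_b <= 1.0):
            raise ValueError(f"target_b out of [0, 1]: {self.target_b}")
        if not (0.0 <= self.target_dist <= 1.0):
            raise ValueError(f"target_dist out of [0, 1]: {self.target_dist}")
        if self.total_occurrences < 1:
            raise ValueError("total_occurrences must be >= 1")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one generated corpus pair; a pure function of itself.

    The same spec (including seed) always yields byte-identical corpora.
    """

    n_docs_pos: int = 9
    n_docs_neg: int = 7
    doc_length_mean: int = 2000
    #: mean document length in the negative corpus; None balances the two
    #: corpora's combined lengths (the typical review setting has nearly
    #: equal total word counts even with unequal document counts)
    doc_length_mean_neg: int | None = None
    vocab_size: int = 4000
    zipf_exponent: float = 1.1
    planted: tuple[PlantedTerm, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_docs_pos", "n_docs_neg", "doc_length_mean", "vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.doc_length_mean_neg is not None and self.doc_length_mean_neg < 1:
            raise ValueError("doc_length_mean_neg must be >= 1")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        terms = [p.term for p in self.planted]
        if len(set(terms)) != len(terms):
            raise ValueError("planted terms must be distinct")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticSpec":
        data = dict(data)
        planted = tuple(PlantedTerm(**p) for p in data.pop("planted", []))
        return cls(planted=planted, **data)

    def to_dict(self) -> dict:
        return {
            "n_docs_pos": self.n_docs_pos,
            "n_docs_neg": self.n_docs_neg,
            "doc_length_mean": self.doc_length_mean,
            "doc_length_mean_neg": self.doc_length_mean_neg,
            "vocab_size": self.vocab_size,
            "zipf_exponent": self.zipf_exponent,
            "seed": self.seed,
            "planted": [
                {
                    "term": p.term,
                    "target_b": p.target_b,
                    "target_dist": p.target_dist,
                    "total_occurrences": p.total_occurrences,
                }
                for p in self.planted
            ],
        }


@dataclass(frozen=True)
class GroundTruth:
    """Realized statistics of one planted term."""

    term: str
    b: float
    dist_fraction: float
    n_pos: int
    n_neg: int
    doc_count_pos: int


def _background_vocab(size: int) -> list[str]:
    # letter-suffixed ids so no normalization rule (plural/verb stripping)
    # can alter them; ranked by Zipf frequency, w0001x most frequent
    return [f"w{i:05d}x" for i in range(1, size + 1)]


def _validate_plants(spec: SyntheticSpec, config: PreprocessConfig) -> None:
    vocab = set(_background_vocab(spec.vocab_size))
    for plant in spec.planted:
        if plant.term in vocab:
            raise ValueError(f"planted term {plant.term!r} collides with background vocabulary")
        if normalize_term(plant.term, config) != [plant.term]:
            raise ValueError(
                f"planted term {plant.term!r} does not survive normalization unchanged; "
                "choose a lowercase, non-stopword, lemma-stable term"
            )


def _plant_allocation(plant: PlantedTerm, n_docs_pos: int) -> tuple[int, int, int]:
    """Split total occurrences into (n_pos, n_neg, n_containing_pos_docs)."""
    n_pos = round(plant.target_b * plant.total_occurrences)
    n_neg = plant.total_occurrences - n_pos
    docs_needed = math.ceil(plant.target_dist * n_docs_pos) if n_pos > 0 else 0
    if n_pos > 0:
        docs_needed = max(1, docs_needed)
    if docs_needed > n_docs_pos:
        raise ValueError(
            f"plant {plant.term!r}: needs {docs_needed} positive documents, only {n_docs_pos} exist"
        )
    if n_pos < docs_needed:
        raise ValueError(
            f"plant {plant.term!r}: {n_pos} positive occurrences cannot cover "
            f"{docs_needed} documents"
        )
    return n_pos, n_neg, docs_needed


def generate_pair(
    spec: SyntheticSpec,
    config: PreprocessConfig | None = None,
) -> tuple[CorpusPair, dict[str, GroundTruth]]:
    """Generate a corpus pair with the spec's planted signal terms.

    Returns the pair plus the realized ground truth per planted term.
    Infeasible plants (more containing documents than exist, or fewer
    occurrences than containing documents) raise before any text is built.
    """
    config = config or PreprocessConfig()
    _validate_plants(spec, config)
    allocations = {p.term: _plant_allocation(p, spec.n_docs_pos) for p in spec.planted}

    rng = np.random.default_rng(spec.seed)
    vocab = np.array(_background_vocab(spec.vocab_size))
    ranks = np.arange(1, spec.vocab_size + 1, dtype=float)
    probs = ranks ** -spec.zipf_exponent
    probs /= probs.sum()

    def _draw_docs(n_docs: int, mean: int) -> list[list[str]]:
        lengths = rng.poisson(mean, size=n_docs)
        lengths = np.maximum(lengths, 1)
        return [list(vocab[rng.choice(spec.vocab_size, size=int(ln), p=probs)]) for ln in lengths]

    neg_mean = spec.doc_length_mean_neg
    if neg_mean is None:
        # balance the corpora's combined lengths by default
        neg_mean = max(1, round(spec.doc_length_mean * spec.n_docs_pos / spec.n_docs_neg))
    pos_tokens = _draw_docs(spec.n_docs_pos, spec.doc_length_mean)
    neg_tokens = _draw_docs(spec.n_docs_neg, neg_mean)

    # free substitution slots per document, so plants never overwrite plants
    pos_free = [list(rng.permutation(len(toks))) for toks in pos_tokens]
    neg_free = [list(rng.permutation(len(toks))) for toks in neg_tokens]

    truth: dict[str, GroundTruth] = {}
    for plant in spec.planted:
        n_pos, n_neg, docs_needed = allocations[plant.term]
        # choose containing positive documents among those with free slots
        candidates = [i for i, free in enumerate(pos_free) if free]
        if len(candidates) < docs_needed:
            raise ValueError(
                f"plant {plant.term!r}: only {len(candidates)} positive documents have "
                "free token slots left"
            )
        chosen = list(rng.choice(len(candidates), size=docs_needed, replace=False))
        chosen_docs = [candidates[i] for i in chosen]
        per_doc = {d: 1 for d in chosen_docs}
        for _ in range(n_pos - docs_needed):
            with_room = [d for d in chosen_docs if per_doc[d] < len(pos_free[d])]
            if not with_room:
                raise ValueError(
                    f"plant {plant.term!r}: positive documents too short for "
                    f"{n_pos} occurrences over {docs_needed} documents"
                )
            per_doc[int(rng.choice(with_room))] += 1
        for d, k in per_doc.items():
            for _ in range(k):
                pos_tokens[d][pos_free[d].pop()] = plant.term
        # negative occurrences: spread over random negative documents
        for _ in range(n_neg):
            with_room = [i for i, free in enumerate(neg_free) if free]
            if not with_room:
                raise ValueError(
                    f"plant {plant.term!r}: negative documents too short for {n_neg} occurrences"
                )
            d = int(rng.choice(with_room))
            neg_tokens[d][neg_free[d].pop()] = plant.term
        total = n_pos + n_neg
        truth[plant.term] = GroundTruth(
            term=plant.term,
            b=n_pos / total,
            dist_fraction=docs_needed / spec.n_docs_pos,
            n_pos=n_pos,
            n_neg=n_neg,
            doc_count_pos=docs_needed,
        )

    width = max(2, len(str(max(spec.n_docs_pos, spec.n_docs_neg))))
    pos_docs = tuple(
        Document(doc_id=f"pos{i + 1:0{width}d}", text=" ".join(toks))
        for i, toks in enumerate(pos_tokens)
    )
    neg_docs = tuple(
        Document(doc_id=f"neg{i + 1:0{width}d}", text=" ".join(toks))
        for i, toks in enumerate(neg_tokens)
    )
    pair = CorpusPair(
        positive=Corpus(label=CorpusLabel.POSITIVE, documents=pos_docs),
        negative=Corpus(label=CorpusLabel.NEGATIVE, documents=neg_docs),
    )
    return pair, truth


def write_pair(
    pair: CorpusPair,
    out_dir: str | Path,
    truth: Mapping[str, GroundTruth] | None = None,
    spec: SyntheticSpec | None = None,
) -> None:
    """Write a pair as two directories of .txt files plus a truth manifest."""
    out_dir = Path(out_dir)
    for corpus, sub in ((pair.positive, "positive"), (pair.negative, "negative")):
        d = out_dir / sub
        d.mkdir(parents=True, exist_ok=True)
        for doc in corpus:
            (d / f"{doc.doc_id}.txt").write_text(doc.text + "\n", encoding="utf-8")
    manifest: dict = {}
    if spec is not None:
        manifest["spec"] = spec.to_dict()
    if truth is not None:
        manifest["ground_truth"] = {
            t: {
                "b": g.b,
                "dist_fraction": g.dist_fraction,
                "n_pos": g.n_pos,
                "n_neg": g.n_neg,
                "doc_count_pos": g.doc_count_pos,
            }
            for t, g in sorted(truth.items())
        }
    (out_dir / "ground_truth.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )


def recovery_report(
    selected: Sequence[TermStatistics | str],
    truth: Mapping[str, GroundTruth],
) -> dict:
    """Precision/recall of planted terms among the selected terms.

    ``rank_of_first_plant`` is the 1-based position of the best-ranked
    planted term in the selection, or None if no plant was selected.
    """
    sel_terms = [s if isinstance(s, str) else s.term for s in selected]
    plants = set(truth)
    hits = [t for t in sel_terms if t in plants]
    precision = len(hits) / len(sel_terms) if sel_terms else (1.0 if not plants else 0.0)
    recall = len(set(hits)) / len(plants) if plants else 1.0
    first = next((i + 1 for i, t in enumerate(sel_terms) if t in plants), None)
    return {
        "precision": precision,
        "recall": recall,
        "rank_of_first_plant": first,
        "n_selected": len(sel_terms),
        "n_planted": len(plants),
    }


def demo_spec(seed: int = 0) -> SyntheticSpec:
    """A small demonstration spec covering the three canonical scenarios."""
    return SyntheticSpec(
        n_docs_pos=9,
        n_docs_neg=7,
        doc_length_mean=800,
        vocab_size=2000,
        zipf_exponent=1.1,
        planted=(
            # ideal: exclusive to the positive corpus and ubiquitous there
            PlantedTerm("zeaxanthinlike", target_b=1.0, target_dist=1.0, total_occurrences=36),
            # strong contrast, but concentrated in one positive document
            PlantedTerm("singledocterm", target_b=0.8, target_dist=1 / 9, total_occurrences=25),
            # balanced occurrence, consistent positive distribution
            PlantedTerm("balancedterm", target_b=0.55, target_dist=1.0, total_occurrences=40),
        ),
        seed=seed,
    )
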