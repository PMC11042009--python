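"""Score a tiny positive/negative corpus pair and select determinants.

Builds two small in-memory corpora of report-like snippets, scores every
term of the positive corpus, and applies the three selection filters
(b > 0.5, score above the 75th percentile, lexicon membership).
"""

from detscore import (
    Corpus,
    CorpusLabel,
    CorpusPair,
    Document,
    Lexicon,
    run_scoring,
)

positive = Corpus(
    label=CorpusLabel.POSITIVE,
    documents=(
        Document("study1", "Zinc and omega-3 supplementation researched. Omega-3 benefits noted."),
        Document("study2", "Participants took omega-3 and lutein. Lutein and zinc intake measured."),
        Document("study3", "Omega-3 rich diets; flavonoids and zinc were considered beneficial."),
    ),
)
negative = Corpus(
    label=CorpusLabel.NEGATIVE,
    documents=(
        Document("study4", "Lutein supplementation showed no significant effect on progression."),
        Document("study5", "No benefit from lutein or vitamins was observed in the trial."),
    ),
)
lexicon = Lexicon(entries=frozenset({"omega-3", "lutein", "zinc", "vitamin"}))

run = run_scoring(CorpusPair(positive, negative), lexicon)

print(f"|B| = {run.manifest['test_set_size']} unique positive-corpus terms")
print(f"75th-percentile score threshold = {run.threshold:.4f}")
print(f"{'term':<12}{'b':>7}{'dist':>7}{'score':>8}")
for s in run.stats[:5]:
    print(f"{s.term:<12}{s.b:>7.3f}{s.dist_fraction:>7.3f}{s.score:>8.3f}")
print("selected determinants:", ", ".join(run.selected_terms) or "(none)")
# b is the share of a term's occurrences falling in the positive corpus,
# dist the share of positive documents containing it; terms high on both
# (here omega-3 and zinc, exclusive to and ubiquitous in the positive
# reports) are flagged, while lutein (more frequent in the negative
# corpus, b <= 0.5) is filtered out however well it scores.
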