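# detscore

Contrastive term scoring between two corpora of research reports: one of
studies reporting significant positive results on a question, one of
studies reporting insignificant or negative results on the same question.
The goal is to surface **potential determinants** — terms (for example,
nutritional compound names) whose presence distinguishes the positive
reports consistently enough to warrant follow-up study — from broad-scope
reports where such terms are rarely prominent topics in the conventional
sense.

## The score

Write the positive corpus as *Cp* and the negative corpus as *Cn*. After
normalization (lowercasing, punctuation stripping, stopword removal,
lemmatization), each document is a multiset of terms. For every term *t*
occurring anywhere in *Cp* (the test set *B*):

- **proportional occurrence** — b(t) = n(t, Cp) / n(t, Cp, Cn), the
  fraction of the term's raw occurrences, pooled over both corpora, that
  fall in *Cp*;
- **document distribution** — DCp(t) / DCp, the fraction of *Cp* documents
  containing the term at least once (multiplicity ignored);
- **determinant score** — a(t) = ( b(t) + DCp(t)/DCp ) / 2, in [0, 1].

A score of 1 means the term never appears in the negative corpus and
appears in every positive document. High b with low distribution means the
excess is attributable to a single document; high distribution with
b ≈ 1/2 means the term is ubiquitous but not contrastive. Candidates are
then filtered three ways: b(t) strictly above 0.5, a(t) strictly above the
75th percentile of all of *B*'s scores, and membership in a user-supplied
lexicon *q* of studyable terms. A classical TF-IDF baseline
(tfidf = f · ln(|D|/DF), per-document dense ranks, cross-corpus mean
ranks) is included to contextualize the selections.

## Worked example

```python
from detscore import Corpus, CorpusLabel, CorpusPair, Document, Lexicon, run_scoring

positive = Corpus(CorpusLabel.POSITIVE, (
    Document("study1", "Zinc and omega-3 supplementation researched. Omega-3 benefits noted."),
    Document("study2", "Participants took omega-3 and lutein. Lutein and zinc intake measured."),
    Document("study3", "Omega-3 rich diets; flavonoids and zinc were considered beneficial."),
))
negative = Corpus(CorpusLabel.NEGATIVE, (
    Document("study4", "Lutein supplementation showed no significant effect on progression."),
    Document("study5", "No benefit from lutein or vitamins was observed in the trial."),
))
lexicon = Lexicon(entries=frozenset({"omega-3", "lutein", "zinc", "vitamin"}))
run = run_scoring(CorpusPair(positive, negative), lexicon)
```

Printing the top of `run.stats` (see `examples/score_corpora.py`) gives:

```
|B| = 16 unique positive-corpus terms
75th-percentile score threshold = 0.6667
term              b   dist   score
omega-3       1.000  1.000   1.000
zinc          1.000  1.000   1.000
beneficial    1.000  0.333   0.667
consider      1.000  0.333   0.667
diet          1.000  0.333   0.667
selected determinants: omega-3, zinc
```

omega-3 and zinc occur only in the positive reports and in all three of
them, so b = dist = 1 and a(t) = 1; they pass all three filters. lutein
scores well on distribution but most of its occurrences are in the
negative corpus (b ≤ 0.5), so the contrast filter removes it regardless of
score — that asymmetry is the point of the method. Terms like
"beneficial" clear the score threshold but are not in the lexicon of
studyable compounds.

The other examples show the TF-IDF baseline (`examples/tfidf_baseline.py`)
and recovery of terms planted in synthetic corpora
(`examples/synthetic_recovery.py`).

## Command line

```sh
detscore score --pos POS_DIR --neg NEG_DIR --lexicon lexicon.txt --out results.tsv
detscore tfidf --pos POS_DIR --neg NEG_DIR --terms terms.txt --out ranks.tsv
detscore simulate --seed 7 --out sim_dir/
```

Each corpus directory holds one UTF-8 `.txt` file per document; the
lexicon is one term per line (multiword entries are dropped with a
warning — the unit of analysis is the unigram). `score` writes the result
table plus a JSON run manifest recording corpus word counts, |B|, the
threshold and per-filter survivor counts; thresholds default to the
method's (75th percentile, b > 0.5) and are overridable.

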