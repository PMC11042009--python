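"""Compare determinant candidates against classical TF-IDF mean ranks.

For each term, every document of a corpus ranks its own terms by
f * ln(|D| / DF) (rank 1 = most prominent) and the term's ranks are
averaged over the documents that contain it, separately per corpus.
"""

from detscore import Corpus, CorpusLabel, Document, mean_rank_table, normalize_corpus

positive = normalize_corpus(Corpus(
    label=CorpusLabel.POSITIVE,
    documents=(
        Document("study1", "zinc zinc omega-3 diet outcomes improved"),
        Document("study2", "omega-3 dosage raised; zinc levels tracked in diet"),
        Document("study3", "diet adherence and omega-3 were studied"),
    ),
))
negative = normalize_corpus(Corpus(
    label=CorpusLabel.NEGATIVE,
    documents=(
        Document("study4", "diet adherence poor, outcomes unchanged"),
        Document("study5", "dosage compliance and diet were studied"),
    ),
))

print(f"{'term':<10}{'mean rank (pos)':>17}{'mean rank (neg)':>17}")
for row in mean_rank_table(["omega-3", "zinc", "diet"], positive, negative):
    fmt = lambda v: "NA" if v is None else f"{v:.1f}"
    print(f"{row.term:<10}{fmt(row.mean_rank_pos):>17}{fmt(row.mean_rank_neg):>17}")
# "NA" means the term never occurs in that corpus, so it has no rank
# there; a term can be a strong determinant candidate yet hold an
# unremarkable TF-IDF rank, which is why the contrastive score exists.
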