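# Methods

## The model

detscore operates on a pair of corpora holding reports with contradictory
conclusions on one research question: *Cp* (significant positive results)
and *Cn* (insignificant/negative results). The unit of analysis is the
normalized unigram. For each term *t* in the test set
*B* = { t ∈ D : D ∈ Cp } the package computes

    b(t)   = n(t, Cp) / n(t, Cp, Cn)          proportional occurrence
    d(t)   = DCp(t) / DCp                     positive-document distribution
    a(t)   = ( b(t) + d(t) ) / 2              determinant score

with n(·) raw multiset counts (no per-document capping, no length
normalization) and DCp(t) the count of positive documents containing the
term at least once. Both components are proportions, so a(t) ∈ [0, 1] and
is strictly increasing in each component; a(t) = 1 iff the term is
*Cp*-exclusive and present in every *Cp* document. Terms confined to *Cn*
are deliberately out of scope: the method asks what distinguishes the
positive reports, not the negative ones.

The score is intentionally indifferent to a term's absolute prominence. A
compound mentioned a handful of times, but only in positive reports and
in most of them, outranks a frequent topic mentioned evenly everywhere.
This is the opposite weighting from TF-IDF, where cross-corpus ubiquity
*suppresses* a term; the bundled TF-IDF baseline exists to make that
contrast measurable (selected determinants typically sit at unremarkable
mean TF-IDF ranks).

Selection applies three pure predicates, order-irrelevant by
construction:

1. b(t) > 0.5 (strict) — the term already leans positive;
2. a(t) > the 75th percentile (strict) of **all** of B's scores, computed
   before any filtering so the threshold describes the full distribution;
3. t ∈ q, the user's lexicon of studyable candidates.

Strict inequalities mean ties at either bound are excluded. The
percentile uses linear interpolation (numpy's default); the method choice
is logged with the threshold so alternates can be compared.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `SelectionConfig.percentile` | 75 | score percentile over B (strict filter) |
| `SelectionConfig.min_proportion` | 0.5 | strict lower bound on b(t) |
| `SelectionConfig.require_lexicon` | true | demand lexicon membership |
| `PreprocessConfig.lemmatizer_mode` | `dictionary` | rule/exception lemmatizer; `identity` disables |
| `PreprocessConfig.keep_internal_hyphens` | true | "omega-3" stays one term |
| `PreprocessConfig.strip_digits` | false | standalone numerals are kept |

Raising the percentile or the proportion bound can only shrink the
selection (anti-monotone; property-tested).

## Normalization

Pipeline order: tokenize → lowercase → strip punctuation → remove
stopwords → lemmatize. Tokens are maximal runs of `[a-z0-9]`, with
internal hyphens kept by default so hyphenated compound names survive as
single terms. `raw_word_count` is the whitespace token count of the
untouched text, taken before any filtering, so reported corpus lengths
match a plain word count of the input files.

The stopword list is a frozen file vendored with the package (about 160
English function words, one per line) rather than pulled from a library
at runtime, so counts cannot drift with an upstream release. Stopwords
are filtered both before and after lemmatization: a lemma can itself be a
function word ("cans" → "can"), and the second pass keeps normalization
idempotent on its own output — an invariant the property tests enforce.

The lemmatizer is a self-contained suffix-detachment scheme (exception
table for irregular forms, then ordered noun-plural and verb-inflection
rules with guards for short, vowel-less or deceptive stems, with
undoubling of final consonants). It is deliberately dictionary-free: with
no word list backing it, some stems are imperfect ("evening" → "even"),
and restored final e's rely on an exception table of common verbs. This
is acceptable for the method because corpus text and the lexicon pass
through the *identical* code path, so candidate matching is unaffected;
but absolute token statistics (test-set sizes, word counts) are
normalization-sensitive and will differ from runs made with other
lemmatizers. The `identity` mode gives raw surface-form counting when
that trade-off is unwanted. One consequence is visible in reporting: a
lexicon entry "Nitrates" and corpus mentions of "nitrates" both normalize
to "nitrate", and results are reported in normalized form.

Multiword lexicon entries ("ascorbic acid") normalize to several tokens
and cannot match the unigram unit of analysis; they are dropped with a
warning and recorded on the `Lexicon` object rather than silently lost.
Phrase matching is a known limitation, not an oversight.

## Synthetic corpora

The generator emulates the target setting: two small corpora (defaults: 9
positive and 7 negative documents) over a shared background vocabulary
with Zipf-distributed frequencies (default exponent 1.1, 4,000 types,
Poisson document lengths with mean 2,000 — review-scale documents sized
so a full run stays interactive). By default the negative corpus's
per-document mean is scaled so both corpora have approximately equal
combined length, matching the near-balanced corpora of the motivating
setting; an explicit `doc_length_mean_neg` overrides this.

Planted terms are placed by substituting background tokens after
background sampling, so document lengths are untouched. Occurrence totals
are split to hit the target b within integer rounding, spread over
⌈target_dist · DCp⌉ distinct positive documents, and the *realized*
statistics are returned as ground truth (exact targets are generally
unreachable for arbitrary totals). Infeasible plants — more containing
documents than occurrences or than documents, terms that normalization
would alter, capacity overruns — fail before any text is built.

What the generator does **not** model: grammar, collocations, section
structure, citation noise, or vocabulary drift between corpora. Passing
recovery tests therefore demonstrates that the statistics and filters
behave as specified under controlled signal, not that the method's
selections on real literature are causally meaningful — the latter
requires follow-up reading of the selected reports, outside any package's
scope.

A property worth knowing when interpreting recovery numbers: with a
lexicon that contains background words, rare background terms can clear
all three filters by sampling noise (a term with three occurrences, all
positive, in two of nine documents scores ≈ 0.61). Precision against
planted truth is therefore an honest measure of that false-positive
channel, not a defect of the recovery harness; the canonical
"concentrated" scenario is likewise *meant* to fall below the threshold,
so scenario-wide recall of 2/3 is the designed outcome.

## Numerical choices

- Ratios are evaluated in double precision from exact integer
  numerators/denominators, which are retained on `TermStatistics` for
  full-precision re-derivation downstream.
- Result tables serialize floats at 4 decimals, sorted by score
  descending with the term string as tie-break, so runs diff cleanly.
- TF-IDF uses the natural log; rankings are provably invariant to the
  base (a positive scalar on all scores) and the suite verifies this by
  recomputing at bases 2 and 10. Per-document ties are broken by higher
  raw frequency, then alphabetically; ranks are dense ordinals 1..k over
  the terms present in the document. Mean ranks average over containing
  documents only — a term absent from a document has no rank there, and a
  term absent from a whole corpus has no mean rank (serialized "NA").
- Degenerate inputs fail loudly: empty corpora, terms absent from both
  corpora (b undefined, never silently 0), f ≥ 1 with DF = 0, empty
  lexicons, empty percentile inputs. An empty *selection* is a valid
  outcome and is logged prominently.

## Known limitations

- Unigrams only; dosages, phrases and multiword compound names are out of
  reach without changing the unit of analysis.
- Raw counts carry no document-length normalization; when the two corpora
  differ in combined length by more than 25% the pipeline logs a warning,
  since b(t) then drifts systematically away from 0.5 for background
  terms. No correction formula is applied.
- A single negative document with many mentions of a term can depress its
  b(t) below the filter even when the term is well distributed across
  positive documents; such cases need case-by-case reading.
- Selection flags association, not causation: a term can be strongly
  associated with positive reports because it is frequently *ruled out*
  in them.
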