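"""Dictionary/rule lemmatization of English tokens.

Term counting treats every surface form of a word as the same topic, so
"nitrate" and "nitrates", or "researched" and "researching", must collapse
to one term before statistics are computed.  The lemmatizer here is a
self-contained suffix-detachment scheme in the classical morphy style: an
exception dictionary of irregular forms is consulted first, then ordered
detachment rules for noun plurals and regular verb inflections are tried,
guarded so that short stems, vowel-less stems and false plurals
("species", "glass", "basis") are left alone.  Nouns take priority, and a
token that matches no rule is returned unchanged.

Because no full dictionary backs the rules, genuinely ambiguous stems
(e.g. restoring a dropped final "e") rely on a small table of common verbs
plus conservative defaults.  Both corpora and the candidate lexicon run
through the identical code path, so matching between them is unaffected by
any residual imprecision; see the package methods note for the trade-offs.

An identity mode is provided for tests and for callers who want raw
surface-form counting.
"""

from __future__ import annotations

__all__ = ["lemmatize", "identity_lemmatize"]

# Irregular forms and common words where pure suffix rules misfire.
_EXCEPTIONS = {
    # irregular noun plurals
    "men": "man", "women": "woman", "children": "child", "people": "person",
    "feet": "foot", "teeth": "tooth", "geese": "goose", "mice": "mouse",
    "lice": "louse", "oxen": "ox", "dice": "die",
    "analyses": "analysis", "bases": "basis", "crises": "crisis",
    "diagnoses": "diagnosis", "hypotheses": "hypothesis", "theses": "thesis",
    "parentheses": "parenthesis", "prognoses": "prognosis",
    "criteria": "criterion", "phenomena": "phenomenon",
    "indices": "index", "matrices": "matrix", "appendices": "appendix",
    "vertices": "vertex", "axes": "axis",
    "fungi": "fungus", "nuclei": "nucleus", "stimuli": "stimulus",
    "bacteria": "bacterium", "media": "medium",
    "genera": "genus", "corpora": "corpus",
    "lives": "life", "knives": "knife", "leaves": "leaf", "halves": "half",
    "wives": "wife", "shelves": "shelf",
    # invariant or deceptive -s / -es words
    "species": "species", "series": "series", "news": "news",
    "diabetes": "diabetes", "lens": "lens", "always": "always",
    "perhaps": "perhaps", "versus": "versus", "its": "its",
    # common verbs whose stems need a restored "e" or resist the rules
    "using": "use", "used": "use", "uses": "use",
    "making": "make", "made": "make",
    "taking": "take", "taken": "take",
    "giving": "give", "given": "give",
    "having": "have", "has": "have", "had": "have",
    "causing": "cause", "caused": "cause",
    "increasing": "increase", "increased": "increase",
    "decreasing": "decrease", "decreased": "decrease",
    "reducing": "reduce", "reduced": "reduce",
    "comparing": "compare", "compared": "compare",
    "analyzing": "analyze", "analyzed": "analyze",
    "determining": "determine", "determined": "determine",
    "measuring": "measure", "measured": "measure",
    "providing": "provide", "provided": "provide",
    "including": "include", "included": "include",
    "requiring": "require", "required": "require",
    "indicating": "indicate", "indicated": "indicate",
    "observing": "observe", "observed": "observe",
    "noting": "note", "noted": "note",
    "dosing": "dose", "dosed": "dose",
    "ageing": "age", "aging": "age", "aged": "age",
    "found": "find", "shown": "show", "seen": "see", "done": "do",
    "was": "be", "were": "be", "been": "be", "being": "be", "is": "be", "are": "be",
    "studies": "study", "studied": "study",
    "based": "base", "related": "relate", "associated": "associate",
    "indeed": "indeed", "hundred": "hundred", "combined": "combine",
}

_VOWELS = set("aeiouy")

# Consonants safe to undouble after stripping -ed/-ing ("planned" -> "plan");
# "ll" and "ss" stay doubled ("falling" -> "fall", "missed" -> "miss").
_UNDOUBLE = set("bdgkmnprtz")


def _has_vowel(s: str) -> bool:
    return any(c in _VOWELS for c in s)


def _undouble(stem: str) -> str:
    if len(stem) >= 4 and stem[-1] == stem[-2] and stem[-1] in _UNDOUBLE:
        return stem[:-1]
    return stem


def _noun_lemma(token: str) -> str | None:
    """Singularise a regular plural noun, or None if no rule applies."""
    if token.endswith(("ss", "us", "is")) or len(token) < 4:
        return None
    for suffix, repl in (("ches", "ch"), ("shes", "sh"), ("xes", "x"),
                         ("zes", "z"), ("sses", "ss")):
        if token.endswith(suffix) and len(token) - len(suffix) >= 2:
            return token[: -len(suffix)] + repl
    if token.endswith("ies") and len(token) >= 5:
        return token[:-3] + "y"
    if token.endswith("oes") and len(token) >= 6:
        return token[:-2]
    if token.endswith("s") and not token.endswith("es"):
        return token[:-1]
    if token.endswith("es"):
        # default: "-es" on a plain stem ("boxes" handled above; "notes" -> "note")
        return token[:-1]
    return None


def _verb_lemma(token: str) -> str | None:
    """Strip a regular -ed/-ing inflection, or None if no rule applies."""
    if token.endswith("ied") and len(token) >= 5:
        return token[:-3] + "y"
    for suffix in ("ing", "ed"):
        if token.endswith(suffix):
            stem = token[: -len(suffix)]
            if len(stem) >= 3 and _has_vowel(stem):
                return _undouble(stem)
    return None


def lemmatize(token: str) -> str:
    """Reduce a single lowercase token to its base form.

    Hyphenated tokens are lemmatized on the final segment only, so
    "omega-3" is untouched and "beta-carotenes" becomes "beta-carotene".
    """
    if not token:
        return token
    if "-" in token:
        head, _, tail = token.rpartition("-")
        return f"{head}-{lemmatize(tail)}" if tail else token
    exc = _EXCEPTIONS.get(token)
    if exc is not None:
        return exc
    if token.isdigit():
        return token
    stem = _noun_lemma(token)
    if stem is None:
        stem = _verb_lemma(token)
    if stem is None:
        return token
    # the stripped stem may itself be irregular ("peoples" -> "people")
    return _EXCEPTIONS.get(stem, stem)


def identity_lemmatize(token: str) -> str:
    """No-op lemmatizer for surface-form counting and tests."""
    return token
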