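"""Lexical, syntactic and disfluency features of patient speech.

Three preprocessing regimes coexist, mirroring how each analysis level is
defined:

* **lexical** — patient speech, disfluency spans removed, lemmatized through a
  pluggable :class:`AnnotatorLexicon` (type–token ratio, lexical density,
  first-person pronoun measures);
* **syntactic** — patient speech, disfluency spans removed, raw surface forms
  (mean words per clause, short answers, truncated clauses);
* **fluency** — verbatim patient speech including disfluency tokens (the
  disfluency proportions use the verbatim word count as denominator).

Undefined ratios (e.g. the subject/object pronoun ratio when no first-person
object pronoun occurs) are returned as NaN, never silently zero; imputation
happens only inside the model stage's training folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Sequence

import pandas as pd

from . import simulate
from .coherence import SemanticSpace, coherence_feature_names, coherence_features
from .transcript import (
    Clause,
    DisfluencyCategory,
    DisfluencySpan,
    MinorUtterance,
    Speaker,
    Transcript,
    strip_disfluency,
)

__all__ = [
    "PosClass",
    "TokenAnnotation",
    "AnnotatorLexicon",
    "synthetic_lexicon",
    "type_token_ratio",
    "lexical_density",
    "pronoun_measures",
    "mean_words_per_clause",
    "short_answer_proportion",
    "disfluency_features",
    "synthetic_study_extractor",
    "extract_features",
    "build_feature_table",
    "FeatureExtractor",
    "FEATURE_NAMES",
    "BASE_FEATURE_NAMES",
]

NA = float("nan")


class PosClass(str, Enum):
    noun = "noun"
    verb = "verb"
    adjective = "adjective"
    adverb = "adverb"
    pronoun_subject_1sg = "pronoun_subject_1sg"
    pronoun_subject_other = "pronoun_subject_other"
    pronoun_object_1sg = "pronoun_object_1sg"
    other_function = "other_function"


CONTENT_CLASSES = frozenset(
    {PosClass.noun, PosClass.verb, PosClass.adjective, PosClass.adverb}
)


@dataclass(frozen=True)
class TokenAnnotation:
    surface: str
    lemma: str
    pos_class: PosClass


@dataclass
class AnnotatorLexicon:
    """Pluggable token annotator.

    The published analyses used an external POS tagger/lemmatizer; bundling
    one would pin the package to a single language, so annotation is a
    lexicon with optional resolver callables.  ``content_resolver`` maps a
    surface form to a :class:`PosClass` (or None for "unknown → function
    word"); ``lemma_resolver`` defaults to identity.
    """

    subject_pronouns: frozenset[str] = frozenset({"je", "tu", "il", "elle", "on", "nous", "vous", "ils", "elles"})
    first_person_subject: frozenset[str] = frozenset({"je"})
    first_person_object: frozenset[str] = frozenset({"me", "moi"})
    content_resolver: Callable[[str], PosClass | None] | None = None
    lemma_resolver: Callable[[str], str] | None = None

    def __post_init__(self):
        if not self.first_person_subject <= self.subject_pronouns:
            raise ValueError("first_person_subject must be a subset of subject_pronouns")

    def annotate(self, surface: str) -> TokenAnnotation:
        tok = surface.lower()
        lemma = self.lemma_resolver(tok) if self.lemma_resolver else tok
        if tok in self.first_person_subject:
            pos = PosClass.pronoun_subject_1sg
        elif tok in self.first_person_object:
            pos = PosClass.pronoun_object_1sg
        elif tok in self.subject_pronouns:
            pos = PosClass.pronoun_subject_other
        else:
            pos = None
            if self.content_resolver is not None:
                pos = self.content_resolver(tok)
            pos = pos or PosClass.other_function
        return TokenAnnotation(surface=tok, lemma=lemma, pos_class=pos)

    def annotate_all(self, tokens: Iterable[str]) -> list[TokenAnnotation]:
        return [self.annotate(t) for t in tokens]


def synthetic_study_extractor(k: int = 8) -> "FeatureExtractor":
    """Feature extractor configured for the synthetic language.

    ``k`` defaults to the generator's latent topic count: with topic structure
    as the only semantic signal, retaining about one dimension per topic is
    the right latent-space scale.
    """
    return FeatureExtractor(
        lexicon=synthetic_lexicon(), k=k, stopwords=simulate.STOPWORDS
    )


def synthetic_lexicon() -> AnnotatorLexicon:
    """Annotator for the generator's pseudo-language.

    Topic/shared vocabulary words are content words (tagged noun); the
    function pool, filled pauses and minor answers are function words.
    """
    function = set(simulate.FUNCTION_WORDS) | set(simulate.FILLED_PAUSE_TOKENS) | set(
        simulate.MINOR_ANSWERS
    )
    pronouns = {"je", "tu", "il", "me", "moi"}

    def resolve(tok: str) -> PosClass | None:
        if tok in function or tok in pronouns:
            return PosClass.other_function
        return PosClass.noun  # topic content word

    return AnnotatorLexicon(
        subject_pronouns=frozenset({"je", "tu", "il"}),
        first_person_subject=frozenset({"je"}),
        first_person_object=frozenset({"me", "moi"}),
        content_resolver=resolve,
    )


# ---------------------------------------------------------------------------
# lexical level


def type_token_ratio(lemmas: Sequence[str]) -> float:
    """Distinct lemmas / total lemmas, in (0, 1]; NaN on empty input."""
    if not lemmas:
        return NA
    return len(set(lemmas)) / len(lemmas)


def lexical_density(tokens: Sequence[TokenAnnotation]) -> float:
    """Content-word (noun/verb/adjective/adverb) fraction of all words."""
    if not tokens:
        return NA
    n_content = sum(1 for t in tokens if t.pos_class in CONTENT_CLASSES)
    return n_content / len(tokens)


def pronoun_measures(tokens: Sequence[TokenAnnotation]) -> tuple[float, float, float]:
    """First-person-singular pronoun measures.

    Returns ``(je_pct_pp, je_pct_total, ratio_subj_obj)``: the share of "I"
    among subject personal pronouns, its share of all words, and the ratio of
    first-person subject to first-person object pronouns.  Undefined
    denominators yield NaN, except the degenerate all-zero case (no "je", no
    subject pronouns, no objects) which is (0, 0, 0).
    """
    if not tokens:
        return NA, NA, NA
    n_je = sum(1 for t in tokens if t.pos_class is PosClass.pronoun_subject_1sg)
    n_subj = n_je + sum(
        1 for t in tokens if t.pos_class is PosClass.pronoun_subject_other
    )
    n_obj = sum(1 for t in tokens if t.pos_class is PosClass.pronoun_object_1sg)
    if n_je == 0 and n_subj == 0 and n_obj == 0:
        return 0.0, 0.0, 0.0
    je_pct_pp = n_je / n_subj if n_subj else NA
    je_pct_total = n_je / len(tokens)
    ratio = n_je / n_obj if n_obj else NA
    return je_pct_pp, je_pct_total, ratio


# ---------------------------------------------------------------------------
# syntactic level


def _patient_clauses(t: Transcript) -> list[Clause]:
    return [el for el in t.iter_elements(Speaker.patient) if isinstance(el, Clause)]


def mean_words_per_clause(t: Transcript) -> float:
    """Mean clause length in words over patient clauses (disfluency stripped).

    Minor utterances are excluded; NaN when the patient produced no clause.
    """
    clauses = [c for c in _patient_clauses(strip_disfluency(t)) if c.word_count > 0]
    if not clauses:
        return NA
    return sum(c.word_count for c in clauses) / len(clauses)


def short_answer_proportion(t: Transcript) -> float:
    """Share of patient turns made only of minor utterances (short answers).

    Disfluency spans are ignored when testing "only minor"; turns with no
    clause and no minor utterance (e.g. pure disfluency) do not count as
    short answers.
    """
    patient_turns = t.patient_turns()
    if not patient_turns:
        return NA
    n_short = 0
    for turn in patient_turns:
        has_minor = any(isinstance(el, MinorUtterance) for el in turn.elements)
        has_clause = any(isinstance(el, Clause) for el in turn.elements)
        if has_minor and not has_clause:
            n_short += 1
    return n_short / len(patient_turns)


# ---------------------------------------------------------------------------
# fluency level


def _patient_word_count(t: Transcript) -> int:
    """Verbatim patient word count, disfluency tokens included."""
    return sum(len(turn.tokens) for turn in t.patient_turns())


def disfluency_features(t: Transcript) -> tuple[float, float, float, float]:
    """(filled_pauses, abandonment, autocorrection_repetition, truncated_clauses_pct).

    Each span counts once regardless of its word count.  The three
    proportions use the verbatim patient word count as denominator;
    ``truncated_clauses_pct`` uses the total patient clause count (full
    clauses plus truncated-clause spans).
    """
    n_words = _patient_word_count(t)
    counts = {cat: 0 for cat in DisfluencyCategory}
    for el in t.iter_elements(Speaker.patient):
        if isinstance(el, DisfluencySpan):
            counts[el.category] += 1
    n_fp = counts[DisfluencyCategory.filled_pause]
    n_ab = counts[DisfluencyCategory.abandonment] + counts[DisfluencyCategory.auto_interruption]
    n_ac = (
        counts[DisfluencyCategory.autocorrection]
        + counts[DisfluencyCategory.repetition]
        + counts[DisfluencyCategory.false_start]
    )
    n_tc = counts[DisfluencyCategory.truncated_clause]
    n_clauses = len([c for c in _patient_clauses(t) if c.word_count > 0]) + n_tc
    if n_words == 0:
        return NA, NA, NA, NA
    tc_pct = n_tc / n_clauses if n_clauses else NA
    return n_fp / n_words, n_ab / n_words, n_ac / n_words, tc_pct


# ---------------------------------------------------------------------------
# assembly

BASE_FEATURE_NAMES = (
    "lexical_diversity",
    "lexical_density",
    "je_pct_pp",
    "je_pct_total",
    "ratio_subj_obj",
    "words_per_clause",
    "short_answers_pct",
    "truncated_clauses_pct",
    "filled_pauses",
    "abandonment",
    "autocorrection_repetition",
)

#: default registry: 11 lexical/syntactic/fluency features + 15 coherence features
FEATURE_NAMES = BASE_FEATURE_NAMES + coherence_feature_names()


def _lexical_tokens(t: Transcript, lexicon: AnnotatorLexicon) -> list[TokenAnnotation]:
    stripped = strip_disfluency(t)
    tokens: list[str] = []
    for turn in stripped.patient_turns():
        tokens.extend(turn.tokens)
    return lexicon.annotate_all(tokens)


def extract_features(
    t: Transcript,
    space: SemanticSpace,
    lexicon: AnnotatorLexicon,
) -> dict[str, float]:
    """All registered features of one transcript as an ordered name→value dict."""
    ann = _lexical_tokens(t, lexicon)
    je_pp, je_total, ratio = pronoun_measures(ann)
    fp, ab, ac, tc = disfluency_features(t)
    vec = {
        "lexical_diversity": type_token_ratio([a.lemma for a in ann]),
        "lexical_density": lexical_density(ann),
        "je_pct_pp": je_pp,
        "je_pct_total": je_total,
        "ratio_subj_obj": ratio,
        "words_per_clause": mean_words_per_clause(t),
        "short_answers_pct": short_answer_proportion(t),
        "truncated_clauses_pct": tc,
        "filled_pauses": fp,
        "abandonment": ab,
        "autocorrection_repetition": ac,
    }
    vec.update(coherence_features(t, space))
    return vec


def build_feature_table(
    transcripts: Sequence[Transcript],
    space: SemanticSpace,
    lexicon: AnnotatorLexicon,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Feature table: one row per transcript, optional ``group`` column."""
    rows = [extract_features(t, space, lexicon) for t in transcripts]
    ids = [t.transcript_id for t in transcripts]
    df = pd.DataFrame(rows, index=pd.Index(ids, name="transcript_id"))
    df = df[list(FEATURE_NAMES)]
    if labels is not None:
        if len(labels) != len(transcripts):
            raise ValueError("labels length mismatch")
        df["group"] = list(labels)
    else:
        inferred = [t.group_label for t in transcripts]
        if all(g is not None for g in inferred):
            df["group"] = inferred
    return df


class FeatureExtractor:
    """sklearn-style transformer: list of Transcripts → feature DataFrame.

    ``fit`` fits the shared latent semantic space on the pooled sentence
    segments of the training transcripts; ``transform`` extracts the full
    feature vector per transcript against that space.
    """

    def __init__(self, lexicon: AnnotatorLexicon | None = None, k: int | None = None,
                 weighting: str = "log_entropy", stopwords: Iterable[str] = ()):
        self.lexicon = lexicon
        self.k = k
        self.weighting = weighting
        self.stopwords = stopwords

    def get_params(self, deep: bool = True) -> dict:
        return {
            "lexicon": self.lexicon,
            "k": self.k,
            "weighting": self.weighting,
            "stopwords": self.stopwords,
        }

    def set_params(self, **params) -> "FeatureExtractor":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: Sequence[Transcript], y=None) -> "FeatureExtractor":
        space = SemanticSpace(k=self.k, weighting=self.weighting, stopwords=self.stopwords)
        space.fit_transcripts(X)
        self.space_ = space
        self.lexicon_ = self.lexicon or synthetic_lexicon()
        return self

    def transform(self, X: Sequence[Transcript]) -> pd.DataFrame:
        if not hasattr(self, "space_"):
            raise RuntimeError("FeatureExtractor is not fitted")
        return build_feature_table(X, self.space_, self.lexicon_)

    def fit_transform(self, X: Sequence[Transcript], y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
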