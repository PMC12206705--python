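"""Synthetic annotated-interview generator with controllable group structure.

Real clinical interview corpora cannot be distributed, so every downstream
stage is exercised on generated transcripts.  The generator emits an
artificial pseudo-language (not French): per-topic content vocabularies with
Zipf-weighted word frequencies, a shared function-word pool, designated
pronoun tokens (``je``, ``me``, ``tu``, ``il``) and filled-pause tokens.

Group-level structure is controlled by a :class:`GroupProfile`:

* semantic coherence via a Markov topic chain — each patient sentence stays
  on the current topic with probability ``topic_persistence`` (rho) and a
  mid-turn "derailment" forces a topic jump with probability
  ``derailment_prob`` (pi) per clause;
* first-person pronoun and disfluency rates, expressed per *verbatim* patient
  word so the extracted feature proportions recover the configured rates;
* clause length, minor-utterance ("short answer") probability and turn count.

Randomness: one root seed; transcript ``i`` draws from
``numpy.random.default_rng([root_seed, i])`` so cohorts are reproducible and
individual transcripts independently re-generable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .transcript import (
    Clause,
    DisfluencyCategory,
    DisfluencySpan,
    MinorUtterance,
    SentenceBoundary,
    Speaker,
    Transcript,
    Turn,
)

__all__ = [
    "TopicModel",
    "GroupProfile",
    "CohortConfig",
    "generate_transcript",
    "generate_cohort",
    "default_profiles",
    "default_cohort_config",
    "FILLED_PAUSE_TOKENS",
    "FUNCTION_WORDS",
    "MINOR_ANSWERS",
    "STOPWORDS",
]

FILLED_PAUSE_TOKENS = ("euh", "hum", "ben")
FUNCTION_WORDS = tuple(f"f{i:02d}" for i in range(12))
MINOR_ANSWERS = ("oui", "non", "voila", "peutetre", "dacc")
_PRONOUNS_SUBJ_1SG = ("je",)
_PRONOUNS_SUBJ_OTHER = ("tu", "il")
_PRONOUNS_OBJ_1SG = ("me", "moi")

#: the synthetic language's stop-word list for the semantic regime: function
#: words, discourse particles and pronouns (as in any French stop list).
#: Filled-pause tokens are NOT stopped — disfluency elements are kept for
#: semantic analyses.
STOPWORDS = frozenset(
    FUNCTION_WORDS
    + MINOR_ANSWERS
    + _PRONOUNS_SUBJ_1SG
    + _PRONOUNS_SUBJ_OTHER
    + _PRONOUNS_OBJ_1SG
)


@dataclass(frozen=True)
class TopicModel:
    """Topic vocabularies standing in for distributional semantic structure.

    Topics are arranged on a line: each topic's own vocabulary is a sliding
    window over a global word list, so *adjacent* topics share
    ``adjacent_overlap_fraction`` of their topic-specific words while distant
    topics share none.  On top of that, a ``shared_vocab_fraction`` of every
    topic's vocabulary is globally shared.  Gradual conversational drift
    (moves to a neighboring topic) therefore keeps consecutive segments
    fairly similar, while a derailment (jump to a distant topic) produces a
    near-orthogonal pair — the structure the coherence minimum responds to.

    Words within a topic are drawn with Zipf rank-frequency weights
    (``weight_r ∝ 1/r^zipf_s``).
    """

    n_topics: int = 8
    vocab_per_topic: int = 24
    shared_vocab_fraction: float = 0.125
    adjacent_overlap_fraction: float = 0.65
    zipf_s: float = 1.0

    def __post_init__(self):
        if self.n_topics < 2:
            raise ValueError("n_topics must be >= 2")
        if self.vocab_per_topic < 20:
            raise ValueError("vocab_per_topic must be >= 20")
        if not 0 <= self.shared_vocab_fraction < 1:
            raise ValueError("shared_vocab_fraction must be in [0, 1)")
        if not 0 <= self.adjacent_overlap_fraction < 1:
            raise ValueError("adjacent_overlap_fraction must be in [0, 1)")
        if self.zipf_s < 0:
            raise ValueError("zipf_s must be >= 0")

    @property
    def n_shared(self) -> int:
        return int(round(self.shared_vocab_fraction * self.vocab_per_topic))

    @property
    def window(self) -> int:
        """Topic-specific words per topic."""
        return self.vocab_per_topic - self.n_shared

    @property
    def step(self) -> int:
        """Window stride between adjacent topics."""
        return max(1, int(round(self.window * (1 - self.adjacent_overlap_fraction))))

    def topic_vocabulary(self, topic: int) -> list[str]:
        """Vocabulary of one topic: globally shared words + its window."""
        if not 0 <= topic < self.n_topics:
            raise ValueError(f"topic {topic} out of range")
        shared = [f"s{i:02d}" for i in range(self.n_shared)]
        start = topic * self.step
        own = [f"w{start + i:03d}" for i in range(self.window)]
        return shared + own

    def word_weights(self) -> np.ndarray:
        """Zipf rank-frequency weights over one topic's window words."""
        w = 1.0 / np.arange(1, self.window + 1) ** self.zipf_s
        return w / w.sum()


@dataclass(frozen=True)
class GroupProfile:
    """Generation parameters for one clinical group.

    Rates are expected proportions per patient word, in the denominator
    regime of the feature that measures them: disfluency rates per *verbatim*
    word (spans included), pronoun rates per *disfluency-stripped* word — so
    the extracted feature proportions recover the configured values directly.
    """

    topic_persistence: float = 0.9
    derailment_prob: float = 0.05
    first_person_subject_rate: float = 0.05
    first_person_object_rate: float = 0.012
    other_subject_pronoun_rate: float = 0.03
    filled_pause_rate: float = 0.02
    abandonment_rate: float = 0.008
    autocorrection_rate: float = 0.008
    truncated_clause_prob: float = 0.3
    clause_length_mean: float = 7.0
    minor_utterance_prob: float = 0.25
    n_turns_mean: int = 80
    content_word_fraction: float = 0.55
    discourse_word_rate: float = 0.08

    def __post_init__(self):
        for name in (
            "topic_persistence",
            "derailment_prob",
            "truncated_clause_prob",
            "minor_utterance_prob",
            "content_word_fraction",
            "discourse_word_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        rates = (
            self.first_person_subject_rate,
            self.first_person_object_rate,
            self.other_subject_pronoun_rate,
            self.filled_pause_rate,
            self.abandonment_rate,
            self.autocorrection_rate,
        )
        if any(r < 0 for r in rates) or sum(rates) >= 1:
            raise ValueError("per-word rates must be >= 0 and sum to < 1")
        if self.clause_length_mean < 1:
            raise ValueError("clause_length_mean must be >= 1")


def default_profiles() -> dict[str, GroupProfile]:
    """Default NAR/AR/FEP profiles.

    The deltas are directional, mirroring the qualitative group contrasts the
    pipeline is meant to recover: the first-episode group derails often
    (low coherence minima), the at-risk group over-uses the first-person
    subject pronoun and under-uses filled pauses, and the not-at-risk group
    is fluent and on-topic.
    """
    nar = GroupProfile(
        topic_persistence=0.88,
        derailment_prob=0.004,
        first_person_subject_rate=0.04,
        filled_pause_rate=0.028,
    )
    ar = replace(
        nar,
        derailment_prob=0.02,
        first_person_subject_rate=0.085,
        filled_pause_rate=0.012,
        abandonment_rate=0.012,
    )
    # derailments are rare but deep: they pin the coherence *minimum* while
    # leaving the median nearly untouched
    fep = replace(
        nar,
        derailment_prob=0.12,
        first_person_subject_rate=0.05,
        filled_pause_rate=0.022,
    )
    return {"NAR": nar, "AR": ar, "FEP": fep}


@dataclass(frozen=True)
class CohortConfig:
    n_per_group: dict = field(default_factory=lambda: {"NAR": 15, "AR": 45, "FEP": 8})
    profiles: dict = field(default_factory=default_profiles)
    topic_model: TopicModel = field(default_factory=TopicModel)
    seed: int = 0

    def __post_init__(self):
        if set(self.n_per_group) != set(self.profiles):
            raise ValueError("n_per_group and profiles must share group labels")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("all group sizes must be positive")


def default_cohort_config(seed: int = 0) -> CohortConfig:
    return CohortConfig(seed=seed)


# span word counts used both for emission and for the rate correction below
_AB_LENGTHS = (2, 3)
_AC_LENGTH = 2
_FP_LENGTH = 1


def _rate_correction(p: GroupProfile) -> float:
    """Expected verbatim words per core word.

    Disfluency spans add words on top of the core clause stream; insertion
    probabilities are scaled by this factor so the configured rates hold per
    *verbatim* word (core + span words), matching the feature denominators.
    """
    mean_ab = float(np.mean(_AB_LENGTHS))
    extra = (
        p.filled_pause_rate * _FP_LENGTH
        + p.abandonment_rate * mean_ab
        + p.autocorrection_rate * _AC_LENGTH
    )
    if extra >= 0.5:
        raise ValueError("disfluency rates too high to calibrate")
    return 1.0 / (1.0 - extra)


def _draw_content_word(rng, topics: TopicModel, topic: int, weights) -> str:
    """Shared global word with prob ``shared_vocab_fraction``, else a
    Zipf-weighted word from the topic's window."""
    vocab = topics.topic_vocabulary(topic)
    n_shared = topics.n_shared
    if n_shared and rng.random() < topics.shared_vocab_fraction:
        return vocab[rng.integers(n_shared)]
    return vocab[n_shared + rng.choice(topics.window, p=weights)]


def _draw_core_word(rng, profile: GroupProfile, topics, topic, weights, corr) -> str:
    """One core (non-span) word: pronoun, content or function token.

    Pronoun rates apply per core word directly: the pronoun features use the
    disfluency-stripped (core) word count as denominator, so no span-word
    correction is wanted here.
    """
    u = rng.random()
    p_je = profile.first_person_subject_rate
    p_me = profile.first_person_object_rate
    p_other = profile.other_subject_pronoun_rate
    if u < p_je:
        return _PRONOUNS_SUBJ_1SG[0]
    u -= p_je
    if u < p_me:
        return _PRONOUNS_OBJ_1SG[rng.integers(len(_PRONOUNS_OBJ_1SG))]
    u -= p_me
    if u < p_other:
        return _PRONOUNS_SUBJ_OTHER[rng.integers(len(_PRONOUNS_SUBJ_OTHER))]
    if rng.random() < profile.discourse_word_rate:
        # discourse particles bleed into clausal speech; they are the only
        # words co-occurring with every topic, which keeps minor-answer
        # segments at moderate (not zero) similarity to topical speech
        return MINOR_ANSWERS[rng.integers(len(MINOR_ANSWERS))]
    if rng.random() < profile.content_word_fraction:
        return _draw_content_word(rng, topics, topic, weights)
    return FUNCTION_WORDS[rng.integers(len(FUNCTION_WORDS))]


def _maybe_spans(rng, profile: GroupProfile, topics, topic, weights, corr, n_words):
    """Disfluency spans to interleave after a clause of ``n_words`` core words."""
    spans = []
    for _ in range(n_words):
        u = rng.random()
        p_fp = profile.filled_pause_rate * corr
        p_ab = profile.abandonment_rate * corr
        p_ac = profile.autocorrection_rate * corr
        if u < p_fp:
            spans.append(
                DisfluencySpan(
                    DisfluencyCategory.filled_pause,
                    FILLED_PAUSE_TOKENS[rng.integers(len(FILLED_PAUSE_TOKENS))],
                )
            )
        elif u < p_fp + p_ab:
            length = _AB_LENGTHS[rng.integers(len(_AB_LENGTHS))]
            words = [_draw_content_word(rng, topics, topic, weights) for _ in range(length)]
            if rng.random() < profile.truncated_clause_prob:
                spans.append(
                    DisfluencySpan(
                        DisfluencyCategory.truncated_clause, " ".join(["je"] + words[:-1])
                    )
                )
            else:
                spans.append(DisfluencySpan(DisfluencyCategory.abandonment, " ".join(words)))
        elif u < p_fp + p_ab + p_ac:
            w = _draw_content_word(rng, topics, topic, weights)
            spans.append(DisfluencySpan(DisfluencyCategory.autocorrection, f"{w} {w}"))
    return spans


def generate_transcript(
    profile: GroupProfile,
    topics: TopicModel | None = None,
    seed: int | np.random.Generator = 0,
    transcript_id: str = "synthetic",
    group_label: str | None = None,
) -> Transcript:
    """Generate one annotated transcript (alternating provider / patient turns)."""
    if profile.n_turns_mean < 2:
        raise ValueError("n_turns_mean must be >= 2")
    topics = topics or TopicModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = topics.word_weights()
    corr = _rate_correction(profile)

    n_pairs = max(1, int(rng.poisson(profile.n_turns_mean / 2)))
    agenda = int(rng.integers(topics.n_topics))
    turns: list[Turn] = []

    def drift(t: int) -> int:
        """Gradual move to a neighboring topic (persistence failure)."""
        if t == 0:
            return 1
        if t == topics.n_topics - 1:
            return t - 1
        return t + (1 if rng.random() < 0.5 else -1)

    def derail(t: int) -> int:
        """Severe jump to a distant topic (beyond any window overlap)."""
        for min_dist in (3, 2, 1):
            far = [k for k in range(topics.n_topics) if abs(k - t) >= min_dist]
            if far:
                return int(far[rng.integers(len(far))])
        raise AssertionError("unreachable: n_topics >= 2")

    for _ in range(n_pairs):
        # the provider pursues a slowly drifting agenda of their own and does
        # not follow patient derailments, so a derailed answer breaks
        # question-answer (turn-level) coherence
        if rng.random() >= profile.topic_persistence:
            agenda = drift(agenda)
        q_words = [_draw_content_word(rng, topics, agenda, weights) for _ in range(6)]
        turns.append(
            Turn(len(turns), Speaker.provider, [Clause(" ".join(q_words) + " ?")])
        )

        if rng.random() < profile.minor_utterance_prob:
            n_ans = 1 + int(rng.integers(3))
            ans = " ".join(
                MINOR_ANSWERS[rng.integers(len(MINOR_ANSWERS))] for _ in range(n_ans)
            )
            turns.append(Turn(len(turns), Speaker.patient, [MinorUtterance(ans)]))
            continue

        # clausal answer: 1-3 clauses, each one sentence, starting on the
        # provider's topic; gradual drift per sentence, and with probability
        # pi a derailment strikes mid-turn — from a random clause onward the
        # rest of the answer is off on a distant topic
        topic = agenda
        elements = []
        n_clauses = int(rng.integers(1, 4))
        derail_at = (
            int(rng.integers(n_clauses))
            if rng.random() < profile.derailment_prob
            else None
        )
        for ci in range(n_clauses):
            if rng.random() >= profile.topic_persistence:
                topic = drift(topic)
            if derail_at is not None and ci == derail_at:
                topic = derail(topic)
            length = 1 + int(rng.poisson(max(profile.clause_length_mean - 1, 0)))
            words = [
                _draw_core_word(rng, profile, topics, topic, weights, corr)
                for _ in range(length)
            ]
            elements.append(Clause(" ".join(words) + " ."))
            elements.extend(_maybe_spans(rng, profile, topics, topic, weights, corr, length))
        turns.append(Turn(len(turns), Speaker.patient, elements))

    return Transcript(
        transcript_id,
        turns,
        group_label=group_label,
        metadata={"generator": "speechmarkers.simulate", "profile_group": group_label},
    )


def generate_cohort(config: CohortConfig) -> tuple[list[Transcript], list[str]]:
    """Generate a full cohort; transcript ``i`` uses child rng ``[seed, i]``."""
    transcripts: list[Transcript] = []
    labels: list[str] = []
    idx = 0
    for group in config.n_per_group:  # insertion order: stable label blocks
        profile = config.profiles[group]
        for _ in range(config.n_per_group[group]):
            rng = np.random.default_rng([config.seed, idx])
            t = generate_transcript(
                profile,
                config.topic_model,
                seed=rng,
                transcript_id=f"synt{idx:03d}",
                group_label=group,
            )
            t.metadata["seed"] = (config.seed, idx)
            transcripts.append(t)
            labels.append(group)
            idx += 1
    return transcripts, labels
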