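"""Latent semantic analysis coherence scoring.

A latent semantic space is a rank-``k`` truncated SVD of a (weighted)
term–document matrix; document similarity is the cosine of the document
embeddings.  Coherence of a transcript is the series of cosines between
*consecutive* segments, computed in three modes:

* ``intersubjective`` — consecutive speech turns (dialogue coherence);
* ``subjective`` — consecutive sentences, both speakers;
* ``subjective_wodr`` — consecutive patient sentences only ("without doctor").

Per series, five summary statistics are reported: median, minimum, IQR and
the percentage of values beyond the Tukey fences at 1.5·IQR on either side.

Semantic preprocessing: tokens are not lemmatized, stop words are removed,
disfluency tokens are kept.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .transcript import Segment, SegmentMode, Transcript, segment

logger = logging.getLogger(__name__)

__all__ = [
    "CoherenceMode",
    "SemanticSpace",
    "fit_semantic_space",
    "SimilaritySeries",
    "similarity_series",
    "CoherenceStats",
    "coherence_stats",
    "coherence_features",
    "coherence_feature_names",
]

#: coherence mode → segmentation mode
MODE_SEGMENTATION = {
    "intersubjective": SegmentMode.turn,
    "subjective": SegmentMode.sentence,
    "subjective_wodr": SegmentMode.patient_sentence,
}
CoherenceMode = str  # one of MODE_SEGMENTATION keys

_WEIGHTINGS = ("raw", "log_entropy", "tfidf")


class SemanticSpace:
    """Latent semantic space (sklearn-style fit/transform estimator).

    Parameters
    ----------
    k:
        Retained dimensions.  Default ``min(100, n_documents - 1, |vocab| - 1)``,
        clipped (with a warning) to the matrix rank bound when larger.
    weighting:
        Term weighting before the SVD: ``log_entropy`` (classic LSA default),
        ``tfidf`` or ``raw``.
    stopwords:
        Terms excluded from the vocabulary entirely.
    """

    def __init__(self, k: int | None = None, weighting: str = "log_entropy",
                 stopwords: Iterable[str] = ()):
        if weighting not in _WEIGHTINGS:
            raise ValueError(f"weighting must be one of {_WEIGHTINGS}")
        self.k = k
        self.weighting = weighting
        self.stopwords = frozenset(w.lower() for w in stopwords)

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "weighting": self.weighting, "stopwords": self.stopwords}

    def set_params(self, **params) -> "SemanticSpace":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            if key == "stopwords":
                value = frozenset(w.lower() for w in value)
            setattr(self, key, value)
        return self

    # -- fitting ------------------------------------------------------------
    def _clean(self, tokens: Iterable[str]) -> list[str]:
        return [t for t in tokens if t not in self.stopwords]

    def fit(self, documents: Sequence[Sequence[str]], y=None) -> "SemanticSpace":
        """Fit on tokenized documents (stop words are removed here)."""
        docs = [self._clean(d) for d in documents]
        docs = [d for d in docs if d]
        if len(docs) < 2:
            raise ValueError("need at least 2 non-empty documents after stop-word removal")
        vocab: dict[str, int] = {}
        for d in docs:
            for t in d:
                vocab.setdefault(t, len(vocab))
        if not vocab:
            raise ValueError("empty vocabulary")
        n_terms, n_docs = len(vocab), len(docs)
        tdm = np.zeros((n_terms, n_docs))
        for j, d in enumerate(docs):
            for t in d:
                tdm[vocab[t], j] += 1.0

        term_weight = np.ones(n_terms)
        if self.weighting == "log_entropy":
            # global weight 1 - H(term)/log(n_docs); local log(1 + tf)
            p = tdm / np.maximum(tdm.sum(axis=1, keepdims=True), 1e-300)
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(p > 0, p * np.log(p), 0.0)
            entropy = -plogp.sum(axis=1)
            term_weight = 1.0 - entropy / np.log(max(n_docs, 2))
            term_weight = np.clip(term_weight, 1e-12, None)
            weighted = np.log1p(tdm) * term_weight[:, None]
        elif self.weighting == "tfidf":
            df = (tdm > 0).sum(axis=1)
            term_weight = np.log((1 + n_docs) / (1 + df)) + 1.0
            weighted = tdm * term_weight[:, None]
        else:
            weighted = tdm

        rank_bound = min(n_terms, n_docs)
        k = self.k if self.k is not None else min(100, n_docs - 1, n_terms - 1)
        k = max(k, 1)
        if k > rank_bound:
            warnings.warn(f"k={k} exceeds rank bound {rank_bound}; clipping")
            k = rank_bound

        # dense SVD: deterministic across runs; corpora here are small
        u, s, vt = np.linalg.svd(weighted, full_matrices=False)
        # sign convention: largest-|.| entry of each right singular vector > 0
        for i in range(vt.shape[0]):
            j = int(np.argmax(np.abs(vt[i])))
            if vt[i, j] < 0:
                vt[i] *= -1.0
                u[:, i] *= -1.0

        self.vocabulary_ = vocab
        self.k_ = k
        self.term_weight_ = term_weight
        self.term_vectors_ = u[:, :k] * s[:k]
        digest = hashlib.sha256()
        for d in docs:
            digest.update(" ".join(d).encode())
            digest.update(b"\n")
        self.fit_corpus_digest_ = digest.hexdigest()[:16]
        return self

    def fit_transcripts(self, transcripts: Sequence[Transcript]) -> "SemanticSpace":
        """Fit on the pooled sentence segments of a transcript corpus."""
        docs = [
            list(seg.text_tokens)
            for t in transcripts
            for seg in segment(t, SegmentMode.sentence)
        ]
        return self.fit(docs)

    # -- embedding ----------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "term_vectors_"):
            raise RuntimeError("SemanticSpace is not fitted")

    def embed(self, tokens: Iterable[str]) -> np.ndarray:
        """Embed a token sequence as the sum of its (weighted) term vectors.

        Out-of-vocabulary and stop-word tokens are ignored; an empty result
        embeds to the zero vector.
        """
        self._check_fitted()
        vec = np.zeros(self.k_)
        for t in self._clean(tokens):
            idx = self.vocabulary_.get(t)
            if idx is not None:
                vec += self.term_vectors_[idx]
        return vec

    def transform(self, documents: Sequence[Sequence[str]]) -> np.ndarray:
        self._check_fitted()
        return np.vstack([self.embed(d) for d in documents])

    def fit_transform(self, documents: Sequence[Sequence[str]], y=None) -> np.ndarray:
        return self.fit(documents).transform(documents)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        self._check_fitted()
        terms = sorted(self.vocabulary_, key=self.vocabulary_.get)
        np.savez(
            path,
            term_vectors=self.term_vectors_,
            term_weight=self.term_weight_,
            vocabulary=json.dumps(terms),
            meta=json.dumps(
                {
                    "k": self.k_,
                    "weighting": self.weighting,
                    "stopwords": sorted(self.stopwords),
                    "fit_corpus_digest": self.fit_corpus_digest_,
                }
            ),
        )

    @classmethod
    def load(cls, path) -> "SemanticSpace":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            terms = json.loads(str(z["vocabulary"]))
            space = cls(k=meta["k"], weighting=meta["weighting"], stopwords=meta["stopwords"])
            space.vocabulary_ = {t: i for i, t in enumerate(terms)}
            space.term_vectors_ = z["term_vectors"]
            space.term_weight_ = z["term_weight"]
            space.k_ = meta["k"]
            space.fit_corpus_digest_ = meta["fit_corpus_digest"]
        return space


def fit_semantic_space(
    documents: Sequence[Sequence[str]],
    k: int | None = None,
    weighting: str = "log_entropy",
    stopwords: Iterable[str] = (),
) -> SemanticSpace:
    """Functional wrapper over :class:`SemanticSpace`."""
    return SemanticSpace(k=k, weighting=weighting, stopwords=stopwords).fit(documents)


@dataclass(frozen=True)
class SimilaritySeries:
    mode: CoherenceMode
    values: tuple[float, ...]
    n_pairs: int

    def __post_init__(self):
        if self.n_pairs != len(self.values):
            raise ValueError("n_pairs must equal len(values)")


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    return float(np.dot(a, b) / (na * nb))


def similarity_series(
    t: Transcript, mode: CoherenceMode, space: SemanticSpace
) -> SimilaritySeries | None:
    """Consecutive-segment cosine series for one transcript.

    Segments embedding to the zero vector (all tokens out-of-vocabulary or
    stopped) are skipped with a log message — a zero vector has no direction,
    so scoring such a pair 0 would fabricate incoherence.  Returns None when
    fewer than two segments are embeddable.
    """
    if mode not in MODE_SEGMENTATION:
        raise ValueError(f"unknown coherence mode {mode!r}")
    segs = segment(t, MODE_SEGMENTATION[mode])
    embeddings = []
    for seg in segs:
        vec = space.embed(seg.text_tokens)
        if np.linalg.norm(vec) == 0.0:
            logger.info(
                "transcript %s: skipping degenerate segment from turn %d",
                t.transcript_id,
                seg.source_turn,
            )
            continue
        embeddings.append(vec)
    if len(embeddings) < 2:
        return None
    values = tuple(
        _cosine(embeddings[i], embeddings[i + 1]) for i in range(len(embeddings) - 1)
    )
    return SimilaritySeries(mode=mode, values=values, n_pairs=len(values))


@dataclass(frozen=True)
class CoherenceStats:
    median: float
    minimum: float
    iqr: float
    pct_above_upper_fence: float
    pct_below_lower_fence: float


def coherence_stats(s: SimilaritySeries | Sequence[float]) -> CoherenceStats:
    """Median, minimum, IQR and Tukey-fence outlier percentages of a series."""
    values = np.asarray(s.values if isinstance(s, SimilaritySeries) else s, dtype=float)
    if values.size < 1:
        raise ValueError("empty similarity series")
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    iqr = q3 - q1
    upper, lower = q3 + 1.5 * iqr, q1 - 1.5 * iqr
    return CoherenceStats(
        median=float(np.median(values)),
        minimum=float(values.min()),
        iqr=float(iqr),
        pct_above_upper_fence=100.0 * float(np.mean(values > upper)),
        pct_below_lower_fence=100.0 * float(np.mean(values < lower)),
    )


_STAT_NAMES = ("median", "minimum", "iqr", "pct_above", "pct_below")
_STAT_ATTRS = ("median", "minimum", "iqr", "pct_above_upper_fence", "pct_below_lower_fence")


def coherence_feature_names() -> tuple[str, ...]:
    """The 15 coherence feature names (3 modes × 5 statistics)."""
    return tuple(
        f"lsa_{mode}_{stat}" for mode in MODE_SEGMENTATION for stat in _STAT_NAMES
    )


def coherence_features(t: Transcript, space: SemanticSpace) -> dict[str, float]:
    """All 15 coherence features of one transcript; NaN where undefined."""
    out: dict[str, float] = {}
    for mode in MODE_SEGMENTATION:
        series = similarity_series(t, mode, space)
        stats = coherence_stats(series) if series is not None else None
        for stat_name, attr in zip(_STAT_NAMES, _STAT_ATTRS):
            out[f"lsa_{mode}_{stat_name}"] = (
                getattr(stats, attr) if stats is not None else float("nan")
            )
    return out
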