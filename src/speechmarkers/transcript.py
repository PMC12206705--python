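"""Parsing, rendering and segmentation of annotated interview transcripts.

Transcripts are plain text in a verbatim annotation dialect: one speech turn
per physical line, healthcare-provider turns wrapped in ``#``, disfluency
spans in ``{}``, clauses (units whose nucleus is a conjugated verb) between
``|`` bars, and minor utterances (no conjugated verb) in ``< >``.

Disfluency spans may carry an explicit category tag, e.g. ``{fp: euh}`` for a
filled pause.  Untagged spans are resolved against a filled-pause lexicon and
otherwise default to ``abandonment`` with a warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Union

logger = logging.getLogger(__name__)

__all__ = [
    "DisfluencyCategory",
    "DisfluencySpan",
    "Clause",
    "MinorUtterance",
    "SentenceBoundary",
    "Speaker",
    "Turn",
    "Transcript",
    "Segment",
    "SegmentMode",
    "ParseError",
    "parse_transcript",
    "render_transcript",
    "read_transcript",
    "write_transcript",
    "segment",
    "strip_disfluency",
    "tokenize",
    "DEFAULT_FILLED_PAUSE_LEXICON",
]

#: vocalized hesitations used to resolve untagged {} spans
DEFAULT_FILLED_PAUSE_LEXICON = frozenset({"euh", "heu", "hum", "ben", "bah"})

_SENTENCE_PUNCT = ".?!…"
_PUNCT_STRIP = _SENTENCE_PUNCT + ",;:"


class ParseError(ValueError):
    """Malformed transcript dialect (unbalanced delimiters, empty file...)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DisfluencyCategory(str, Enum):
    filled_pause = "filled_pause"
    repetition = "repetition"
    false_start = "false_start"
    autocorrection = "autocorrection"
    auto_interruption = "auto_interruption"
    abandonment = "abandonment"
    truncated_clause = "truncated_clause"


#: dialect tag ↔ category
_TAG_TO_CATEGORY = {
    "fp": DisfluencyCategory.filled_pause,
    "rep": DisfluencyCategory.repetition,
    "fs": DisfluencyCategory.false_start,
    "ac": DisfluencyCategory.autocorrection,
    "ai": DisfluencyCategory.auto_interruption,
    "ab": DisfluencyCategory.abandonment,
    "tc": DisfluencyCategory.truncated_clause,
}
_CATEGORY_TO_TAG = {v: k for k, v in _TAG_TO_CATEGORY.items()}


class Speaker(str, Enum):
    patient = "patient"
    provider = "provider"


def tokenize(text: str) -> list[str]:
    """Whitespace-split, strip terminal punctuation, lowercase.

    Tokens that are pure punctuation are dropped.
    """
    out = []
    for raw in text.split():
        tok = raw.strip(_PUNCT_STRIP).lower()
        if tok:
            out.append(tok)
    return out


def _norm_text(text: str) -> str:
    return " ".join(text.split())


@dataclass(frozen=True)
class DisfluencySpan:
    """A ``{}`` span; counted as one disfluency element regardless of length."""

    category: DisfluencyCategory
    text: str  # raw inner text, whitespace-normalized

    @property
    def tokens(self) -> list[str]:
        return tokenize(self.text)

    @property
    def word_count(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Clause:
    """A ``|...|`` clause whose nucleus is (by annotation) a conjugated verb."""

    text: str
    is_truncated: bool = False

    @property
    def tokens(self) -> list[str]:
        return tokenize(self.text)

    @property
    def word_count(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class MinorUtterance:
    """A ``< >`` speech unit with no conjugated verb ("oui", "pas vraiment")."""

    text: str

    @property
    def tokens(self) -> list[str]:
        return tokenize(self.text)


@dataclass(frozen=True)
class SentenceBoundary:
    """Bare terminal punctuation between marked-up elements."""

    mark: str = "."


TurnElement = Union[Clause, MinorUtterance, DisfluencySpan, SentenceBoundary]


@dataclass
class Turn:
    index: int
    speaker: Speaker
    elements: list[TurnElement]
    raw_text: str = field(default="", compare=False)

    @property
    def text(self) -> str:
        """Verbatim turn text with annotation symbols removed."""
        parts = []
        for el in self.elements:
            if isinstance(el, SentenceBoundary):
                parts.append(el.mark)
            else:
                parts.append(el.text)
        return _norm_text(" ".join(parts))

    @property
    def tokens(self) -> list[str]:
        return tokenize(self.text)

    def is_empty(self) -> bool:
        return not self.text.strip()


@dataclass
class Transcript:
    transcript_id: str
    turns: list[Turn]
    group_label: str | None = None
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for i, t in enumerate(self.turns):
            if t.index != i:
                raise ValueError("turn indices must be consecutive from 0")
        if not any(t.speaker is Speaker.patient for t in self.turns):
            raise ValueError("transcript must contain at least one patient turn")

    def patient_turns(self) -> list[Turn]:
        return [t for t in self.turns if t.speaker is Speaker.patient]

    def iter_elements(self, speaker: Speaker | None = None) -> Iterator[TurnElement]:
        for t in self.turns:
            if speaker is None or t.speaker is speaker:
                yield from t.elements


class SegmentMode(str, Enum):
    turn = "turn"
    sentence = "sentence"
    patient_sentence = "patient_sentence"


@dataclass(frozen=True)
class Segment:
    text_tokens: tuple[str, ...]
    speaker: Speaker
    source_turn: int
    mode: SegmentMode


_SPAN_RE = re.compile(r"\{([^{}]*)\}")
_MINOR_RE = re.compile(r"<([^<>]*)>")
_TAG_RE = re.compile(r"^\s*(fp|rep|fs|ac|ai|ab|tc)\s*:\s*(.*)$", re.DOTALL)


def _resolve_span(inner: str, line_no: int, filled_pause_lexicon) -> DisfluencySpan:
    m = _TAG_RE.match(inner)
    if m:
        cat = _TAG_TO_CATEGORY[m.group(1)]
        body = _norm_text(m.group(2))
        if not body:
            raise ParseError("empty disfluency span", line_no)
        return DisfluencySpan(cat, body)
    body = _norm_text(inner)
    if not body:
        raise ParseError("empty disfluency span", line_no)
    toks = tokenize(body)
    if toks and all(t in filled_pause_lexicon for t in toks):
        return DisfluencySpan(DisfluencyCategory.filled_pause, body)
    logger.warning(
        "line %d: untagged disfluency span %r not in filled-pause lexicon; "
        "assigning category 'abandonment'",
        line_no,
        body,
    )
    return DisfluencySpan(DisfluencyCategory.abandonment, body)


def _check_balance(line: str, line_no: int) -> None:
    for opener, closer in ("{}", "<>"):
        depth = 0
        for ch in line:
            if ch == opener:
                depth += 1
                if depth > 1:
                    raise ParseError(f"nested '{opener}'", line_no)
            elif ch == closer:
                depth -= 1
                if depth < 0:
                    raise ParseError(f"unbalanced '{closer}'", line_no)
        if depth != 0:
            raise ParseError(f"unbalanced '{opener}'", line_no)
    if line.count("|") % 2 != 0:
        raise ParseError("unbalanced '|' (odd number of clause bars)", line_no)


def _parse_patient_line(line: str, line_no: int, filled_pause_lexicon) -> list[TurnElement]:
    _check_balance(line, line_no)
    elements: list[TurnElement] = []

    # scan left to right: {...} spans, <...> minors, |...| clauses, bare text
    pos = 0
    n = len(line)
    while pos < n:
        ch = line[pos]
        if ch.isspace():
            pos += 1
            continue
        if ch == "{":
            end = line.index("}", pos)
            elements.append(_resolve_span(line[pos + 1 : end], line_no, filled_pause_lexicon))
            pos = end + 1
        elif ch == "<":
            end = line.index(">", pos)
            inner = _norm_text(line[pos + 1 : end])
            if "|" in inner:
                raise ParseError("clause bar inside minor utterance", line_no)
            if inner:
                elements.append(MinorUtterance(inner))
            pos = end + 1
        elif ch == "|":
            end = line.index("|", pos + 1)
            inner = line[pos + 1 : end]
            if "{" in inner or "<" in inner:
                # disfluency or minor markup inside the clause bars: split out
                sub = _parse_patient_line(inner, line_no, filled_pause_lexicon)
                for el in sub:
                    elements.append(el)
            else:
                body = _norm_text(inner)
                if body:
                    elements.append(Clause(body))
            pos = end + 1
        else:
            # bare run up to the next markup symbol
            m = re.compile(r"[{<|]").search(line, pos)
            end = m.start() if m else n
            bare = _norm_text(line[pos:end])
            pos = end
            if not bare:
                continue
            if all(c in _PUNCT_STRIP or c.isspace() for c in bare):
                for c in bare:
                    if c in _SENTENCE_PUNCT:
                        elements.append(SentenceBoundary(c))
            else:
                logger.warning(
                    "line %d: bare text %r outside markup; treating as clause", line_no, bare
                )
                elements.append(Clause(bare))
    return elements


def parse_transcript(
    text: str,
    transcript_id: str = "transcript",
    group_label: str | None = None,
    filled_pause_lexicon: Iterable[str] = DEFAULT_FILLED_PAUSE_LEXICON,
) -> Transcript:
    """Parse dialect text into a :class:`Transcript`.

    Raises :class:`ParseError` (with a line number) on unbalanced delimiters,
    an odd number of ``#`` on a line, or an empty file.
    """
    lexicon = frozenset(w.lower() for w in filled_pause_lexicon)
    turns: list[Turn] = []
    saw_content = False
    for line_no, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.strip()
        if not line:
            continue
        saw_content = True
        n_hash = line.count("#")
        if n_hash:
            if n_hash % 2 != 0 or not (line.startswith("#") and line.endswith("#")):
                raise ParseError("odd or misplaced '#' delimiters", line_no)
            inner = line[1:-1].strip()
            # provider speech carries no clause/minor markup; keep as one clause
            elements: list[TurnElement] = [Clause(_norm_text(inner))] if inner else []
            turns.append(Turn(len(turns), Speaker.provider, elements, raw_text=raw_line))
        else:
            elements = _parse_patient_line(line, line_no, lexicon)
            turns.append(Turn(len(turns), Speaker.patient, elements, raw_text=raw_line))
    if not saw_content:
        raise ParseError("empty transcript file")
    return Transcript(transcript_id, turns, group_label=group_label)


def _render_element(el: TurnElement) -> str:
    if isinstance(el, DisfluencySpan):
        return "{%s: %s}" % (_CATEGORY_TO_TAG[el.category], el.text)
    if isinstance(el, Clause):
        return f"| {el.text} |"
    if isinstance(el, MinorUtterance):
        return f"< {el.text} >"
    if isinstance(el, SentenceBoundary):
        return el.mark
    raise TypeError(f"unknown element {el!r}")


def render_transcript(t: Transcript) -> str:
    """Render a Transcript back to dialect text; ``parse(render(t)) == t``."""
    lines = []
    for turn in t.turns:
        if turn.speaker is Speaker.provider:
            inner = " ".join(el.text for el in turn.elements)
            lines.append(f"# {inner} #" if inner else "# #")
        else:
            lines.append(" ".join(_render_element(el) for el in turn.elements))
    return "\n".join(lines) + "\n"


def read_transcript(path, **kwargs) -> Transcript:
    from pathlib import Path

    p = Path(path)
    tid = kwargs.pop("transcript_id", p.stem)
    return parse_transcript(p.read_text(encoding="utf-8"), transcript_id=tid, **kwargs)


def write_transcript(t: Transcript, path) -> None:
    from pathlib import Path

    Path(path).write_text(render_transcript(t), encoding="utf-8")


def _sentence_split(text: str) -> list[str]:
    """Split on terminal punctuation runs (., ?, !, ellipsis) and line end."""
    parts = re.split(r"[%s]+" % re.escape(_SENTENCE_PUNCT), text)
    return [p for p in (s.strip() for s in parts) if p]


def segment(t: Transcript, mode: SegmentMode | str) -> list[Segment]:
    """Segment a transcript one of three ways.

    ``turn``: one segment per non-empty turn (both speakers).
    ``sentence``: terminal-punctuation split across both speakers in order.
    ``patient_sentence``: provider turns dropped first, then sentence split.

    Disfluency tokens are kept in segment text (they are removed only by the
    syntactic/lexical preprocessing regimes, not here).
    """
    mode = SegmentMode(mode)
    segments: list[Segment] = []
    for turn in t.turns:
        if mode is SegmentMode.patient_sentence and turn.speaker is Speaker.provider:
            continue
        text = turn.text
        if not text:
            continue
        if mode is SegmentMode.turn:
            pieces = [text]
        else:
            pieces = _sentence_split(text)
        for piece in pieces:
            toks = tuple(tokenize(piece))
            if toks:
                segments.append(Segment(toks, turn.speaker, turn.index, mode))
    return segments


def strip_disfluency(t: Transcript) -> Transcript:
    """Remove every disfluency span; clause and minor markup is preserved."""
    new_turns = []
    for turn in t.turns:
        els = [el for el in turn.elements if not isinstance(el, DisfluencySpan)]
        new_turns.append(Turn(turn.index, turn.speaker, els, raw_text=turn.raw_text))
    return Transcript(
        t.transcript_id, new_turns, group_label=t.group_label, metadata=dict(t.metadata)
    )
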