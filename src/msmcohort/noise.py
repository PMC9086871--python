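"""Retweet and reported-speech filtering.

Matches against text that merely repeats someone else's words — retweets,
quotations, attributed statements, news headlines — are not self-reports.
Retweet removal is a blanket pre-filter on the stream; reported-speech
detection is span-conditional (it needs the location of a candidate match
inside the text) and therefore runs at match time.

The reported-speech detector is a three-rule heuristic, each rule
independently toggleable:

``quotation``
    the candidate span lies inside a quotation-mark-delimited region
    (straight or curly double quotes; an unbalanced opening quote closes
    at end-of-text);
``attribution``
    the sentence containing the span ends with an attribution verb
    pattern (said / says / told / wrote / tweeted ..., with an optional
    subject);
``headline``
    the text reads like a news headline: no first-person pronoun
    anywhere, ends with a URL, and title-case density above a configured
    threshold (default 0.10 — headlines in tweet streams are usually
    sentence-case, so the density clause is a weak corroborator rather
    than the main signal).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .records import TweetRecord

__all__ = [
    "FilterVerdict",
    "FilterDecision",
    "ReportedSpeechConfig",
    "is_retweet",
    "quote_regions",
    "detect_reported_speech",
    "filter_stream",
]


class FilterVerdict(str, Enum):
    RETAIN = "retain"
    DROP_RETWEET = "drop_retweet"
    DROP_REPORTED_SPEECH = "drop_reported_speech"


@dataclass(frozen=True)
class FilterDecision:
    tweet_id: str
    verdict: FilterVerdict
    trigger: str = ""

    def __post_init__(self) -> None:
        if self.verdict is not FilterVerdict.RETAIN and not self.trigger:
            raise ValueError("drop verdicts must carry a trigger")


@dataclass
class ReportedSpeechConfig:
    """Rule toggles and the headline title-case threshold."""

    quotation: bool = True
    attribution: bool = True
    headline: bool = True
    titlecase_threshold: float = 0.10


_OPEN_QUOTES = '"“'
_CLOSE_QUOTES = '"”'

_ATTRIBUTION_VERBS = (
    "said|says|say|told|tells|wrote|writes|tweeted|tweets|"
    "reported|reports|announced|announces|claimed|claims|stated|states"
)
# optional subject (pronoun or single capitalized-or-not word) + verb at
# sentence end, e.g. ', he said.'  or '... says'.
_ATTRIBUTION_RE = re.compile(
    r"[,—-]?\s*(?:\w+\s+)?(?:%s)\s*[.!?…]*\s*$" % _ATTRIBUTION_VERBS,
    re.IGNORECASE,
)

_FIRST_PERSON_RE = re.compile(
    r"\b(?:i|me|my|mine|myself|we|us|our|ours|ourselves|i'm|i've|i'd|i'll)\b",
    re.IGNORECASE,
)
_URL_END_RE = re.compile(r"https?://\S+\s*$")
_SENTENCE_SPLIT_RE = re.compile(r"(?<=[.!?…])\s+")
_WORD_RE = re.compile(r"[A-Za-z][A-Za-z'’]*")


def is_retweet(t: TweetRecord) -> bool:
    """True iff the normalized retweet flag is set.

    Quote-tweets are not retweets; they are judged by the span rule in
    :func:`detect_reported_speech`.
    """
    return t.is_retweet


def quote_regions(text: str) -> list[tuple[int, int]]:
    """Half-open intervals of quotation-mark-delimited regions.

    Straight and curly double quotes are recognized; an unbalanced
    opening quote closes at end-of-text.
    """
    regions: list[tuple[int, int]] = []
    open_at: int | None = None
    for i, ch in enumerate(text):
        if open_at is None:
            if ch in _OPEN_QUOTES:
                open_at = i + 1
        else:
            if ch in _CLOSE_QUOTES:
                regions.append((open_at, i))
                open_at = None
    if open_at is not None:
        regions.append((open_at, len(text)))
    return regions


def _sentence_bounds(text: str, pos: int) -> tuple[int, int]:
    start = 0
    for m in re.finditer(r"[.!?…]+\s+", text):
        if m.end() <= pos:
            start = m.end()
        else:
            break
    end = len(text)
    m = re.search(r"[.!?…]", text[pos:])
    if m:
        end = pos + m.start() + 1
        # extend over a run of terminal punctuation
        while end < len(text) and text[end] in ".!?…":
            end += 1
    return start, end


def _titlecase_density(text: str) -> float:
    # URLs are not words; don't let them dilute the density
    text = re.sub(r"https?://\S+", "", text)
    words = [w for w in _WORD_RE.findall(text)]
    if not words:
        return 0.0
    title = sum(1 for w in words if w[0].isupper())
    return title / len(words)


def detect_reported_speech(
    text: str,
    span: tuple[int, int],
    config: ReportedSpeechConfig | None = None,
) -> tuple[bool, str]:
    """Decide whether the candidate match at ``span`` is reported speech.

    Returns ``(flag, trigger)`` where trigger names the rule that fired
    (``quotation``, ``attribution`` or ``headline``) or is empty.
    Raises ``ValueError`` for an invalid span.
    """
    cfg = config or ReportedSpeechConfig()
    start, end = span
    if not (0 <= start <= end <= len(text)):
        raise ValueError(f"span {span!r} outside text of length {len(text)}")

    if cfg.quotation:
        for qs, qe in quote_regions(text):
            if start >= qs and end <= qe:
                return True, "quotation"

    if cfg.attribution:
        s_start, s_end = _sentence_bounds(text, start)
        sentence = text[s_start:s_end]
        if _ATTRIBUTION_RE.search(sentence):
            return True, "attribution"

    if cfg.headline:
        if (
            not _FIRST_PERSON_RE.search(text)
            and _URL_END_RE.search(text)
            and _titlecase_density(text) > cfg.titlecase_threshold
        ):
            return True, "headline"

    return False, ""


def filter_stream(
    records: Iterable[TweetRecord],
) -> tuple[list[TweetRecord], list[FilterDecision]]:
    """Blanket retweet pre-filter.

    Emits one decision per input record, order preserved.  Reported
    speech is span-conditional and handled downstream at match time.
    """
    retained: list[TweetRecord] = []
    decisions: list[FilterDecision] = []
    for rec in records:
        if is_retweet(rec):
            decisions.append(
                FilterDecision(rec.tweet_id, FilterVerdict.DROP_RETWEET, "retweet_flag")
            )
        else:
            decisions.append(FilterDecision(rec.tweet_id, FilterVerdict.RETAIN))
            retained.append(rec)
    return retained, decisions
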