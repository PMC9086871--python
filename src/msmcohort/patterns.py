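"""Self-report pattern grammar: compilation and matching.

The matcher identifies first-person self-reports of being gay, bisexual
or MSM.  Patterns are handwritten for precision, not recall: an identity
term alone ("I love my gay friends") never matches — a first-person
anchor ("I'm a ...", "as a ...", "... like me", "being a ...") is
required in tweet text.  Profile descriptions are self-descriptive by
convention, so the profile channel only requires an identity+person
collocation ("proud black gay guy").

The grammar is config-resident (YAML): term lists plus templates whose
placeholders expand to a finite cross-product of surface patterns.  The
default operating mode deliberately matches third-person memorials and
trans/nonbinary profiles — the pipeline's measured precision is defined
against that behavior, and the annotation layer, not the matcher,
separates true from false positives.  ``mode="strict"`` adds exclusion
rules (third-person possessives in the match sentence; trans/nonbinary
profile terms) that raise precision at the cost of recall.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Literal, Sequence

import yaml

from .noise import ReportedSpeechConfig, detect_reported_speech, _sentence_bounds
from .records import TweetRecord, UserRecord

__all__ = [
    "Channel",
    "MatchResult",
    "PatternSet",
    "SelfReportEvidence",
    "PatternConfigError",
    "load_default_config",
    "compile_pattern_set",
    "match_tweet_text",
    "match_profile",
    "classify_user",
]

_PLACEHOLDER_RE = re.compile(r"\{(\w+)\}")
_KNOWN_PLACEHOLDERS = {"identity", "person", "person_or_people"}


class PatternConfigError(ValueError):
    """Malformed pattern configuration (empty term list, bad placeholder)."""


class Channel(str, Enum):
    TWEET = "tweet"
    PROFILE = "profile"
    BOTH = "both"


@dataclass(frozen=True)
class MatchResult:
    channel: Channel
    matched_span: tuple[int, int]
    template_id: str
    matched_text: str


@dataclass(frozen=True)
class _SurfacePattern:
    template_id: str
    regex: re.Pattern
    order: int


@dataclass
class PatternSet:
    """Compiled matchers for both channels plus the raw term lists."""

    identity_terms: list[str]
    person_terms: list[str]
    collective_terms: list[str]
    tweet_patterns: list[_SurfacePattern]
    profile_patterns: list[_SurfacePattern]
    prefilter: re.Pattern
    third_person_re: re.Pattern | None = None
    transnb_re: re.Pattern | None = None

    @property
    def n_surface_patterns(self) -> int:
        return len(self.tweet_patterns) + len(self.profile_patterns)


def load_default_config() -> dict:
    """The pattern grammar shipped in the package data directory."""
    text = (
        resources.files("msmcohort").joinpath("data/patterns.yaml").read_text("utf-8")
    )
    return yaml.safe_load(text)


def _term_fragment(term: str) -> str:
    # multi-word terms match across any whitespace
    return r"\s+".join(re.escape(tok) for tok in term.split())


def _expand_template(
    template_id: str,
    pattern: str,
    identity_terms: Sequence[str],
    person_terms: Sequence[str],
    collective_terms: Sequence[str],
    order_start: int,
) -> list[_SurfacePattern]:
    placeholders = set(_PLACEHOLDER_RE.findall(pattern))
    unknown = placeholders - _KNOWN_PLACEHOLDERS
    if unknown:
        raise PatternConfigError(
            f"template {template_id!r}: unknown placeholder(s) {sorted(unknown)}"
        )

    identity_opts = identity_terms if "identity" in placeholders else [None]
    if "person_or_people" in placeholders:
        person_opts: Sequence[str | None] = list(person_terms) + list(collective_terms)
        person_key = "person_or_people"
    elif "person" in placeholders:
        person_opts = list(person_terms)
        person_key = "person"
    else:
        person_opts = [None]
        person_key = None

    out: list[_SurfacePattern] = []
    order = order_start
    for ident in identity_opts:
        for person in person_opts:
            filled = pattern
            if ident is not None:
                filled = filled.replace("{identity}", _term_fragment(ident))
            if person_key is not None and person is not None:
                filled = filled.replace("{" + person_key + "}", _term_fragment(person))
            try:
                rx = re.compile(r"\b(?:" + filled + r")\b", re.IGNORECASE)
            except re.error as exc:
                raise PatternConfigError(
                    f"template {template_id!r} does not compile: {exc}"
                ) from exc
            out.append(_SurfacePattern(template_id, rx, order))
            order += 1
    return out


def compile_pattern_set(config: dict | None = None) -> PatternSet:
    """Compile the pattern grammar into a :class:`PatternSet`.

    Expansion is deterministic: with N identity terms and M person terms
    a ``{identity}...{person}`` template yields the full N x M
    cross-product of surface patterns.
    """
    cfg = config if config is not None else load_default_config()

    identity = list(cfg.get("identity_terms") or [])
    person = list(cfg.get("person_terms") or [])
    collective = list(cfg.get("collective_terms") or [])
    tweet_templates = list(cfg.get("tweet_templates") or [])
    profile_templates = list(cfg.get("profile_templates") or [])

    if not identity:
        raise PatternConfigError("identity_terms must be non-empty")
    if not person:
        raise PatternConfigError("person_terms must be non-empty")
    if not tweet_templates or not profile_templates:
        raise PatternConfigError("at least one template per channel is required")

    tweet_patterns: list[_SurfacePattern] = []
    for tmpl in tweet_templates:
        tweet_patterns.extend(
            _expand_template(
                tmpl["id"], tmpl["pattern"], identity, person, collective,
                order_start=len(tweet_patterns),
            )
        )
    profile_patterns: list[_SurfacePattern] = []
    for tmpl in profile_templates:
        profile_patterns.extend(
            _expand_template(
                tmpl["id"], tmpl["pattern"], identity, person, collective,
                order_start=len(profile_patterns),
            )
        )

    # cheap rejection: a text without any identity term cannot match
    prefilter = re.compile(
        r"\b(?:" + "|".join(_term_fragment(t) for t in identity) + r")\b",
        re.IGNORECASE,
    )

    strict = cfg.get("strict_exclusions") or {}
    third_person = strict.get("third_person_possessives") or []
    transnb = strict.get("transnb_profile_terms") or []
    third_person_re = (
        re.compile(r"\b(?:" + "|".join(map(re.escape, third_person)) + r")\b", re.I)
        if third_person
        else None
    )
    transnb_re = (
        re.compile(r"\b(?:" + "|".join(map(re.escape, transnb)) + r")\b", re.I)
        if transnb
        else None
    )

    return PatternSet(
        identity_terms=identity,
        person_terms=person,
        collective_terms=collective,
        tweet_patterns=tweet_patterns,
        profile_patterns=profile_patterns,
        prefilter=prefilter,
        third_person_re=third_person_re,
        transnb_re=transnb_re,
    )


def _leftmost(
    text: str, patterns: Sequence[_SurfacePattern], channel: Channel
) -> MatchResult | None:
    best: tuple[int, int] | None = None  # (start, order)
    best_match: MatchResult | None = None
    for sp in patterns:
        m = sp.regex.search(text)
        if m is None:
            continue
        key = (m.start(), sp.order)
        if best is None or key < best:
            best = key
            best_match = MatchResult(
                channel=channel,
                matched_span=(m.start(), m.end()),
                template_id=sp.template_id,
                matched_text=text[m.start() : m.end()],
            )
    return best_match


def match_tweet_text(
    text: str, ps: PatternSet, mode: Literal["default", "strict"] = "default"
) -> MatchResult | None:
    """Leftmost self-report match in tweet text, or None.

    Overlapping templates are resolved by template list order.  In
    strict mode a match whose sentence contains a third-person
    possessive before the span is suppressed.
    """
    if not ps.prefilter.search(text):
        return None
    m = _leftmost(text, ps.tweet_patterns, Channel.TWEET)
    if m is None:
        return None
    if mode == "strict" and ps.third_person_re is not None:
        s_start, _ = _sentence_bounds(text, m.matched_span[0])
        preceding = text[s_start : m.matched_span[0]]
        if ps.third_person_re.search(preceding):
            return None
    return m


def match_profile(
    user: UserRecord, ps: PatternSet, mode: Literal["default", "strict"] = "default"
) -> MatchResult | None:
    """Leftmost match over the profile description, then display name."""
    for text in (user.user_description, user.user_name):
        if not text or not ps.prefilter.search(text):
            continue
        m = _leftmost(text, ps.profile_patterns, Channel.PROFILE)
        if m is None:
            continue
        if mode == "strict" and ps.transnb_re is not None:
            if ps.transnb_re.search(user.user_description) or ps.transnb_re.search(
                user.user_name
            ):
                return None
        return m
    return None


@dataclass(frozen=True)
class SelfReportEvidence:
    """Why a user entered the cohort: channel(s) plus provenance."""

    user_id: str
    channel: Channel
    tweet_match: MatchResult | None = None
    tweet_id: str | None = None  # earliest matching, non-reported-speech tweet
    profile_match: MatchResult | None = None


def classify_user(
    tweets: Iterable[TweetRecord],
    user: UserRecord,
    ps: PatternSet,
    speech_config: ReportedSpeechConfig | None = None,
    mode: Literal["default", "strict"] = "default",
) -> SelfReportEvidence | None:
    """Classify one user from their retweet-filtered tweets and profile.

    The evidence channel is ``tweet`` if any non-reported-speech tweet
    matches, ``profile`` if the profile matches, ``both`` if both; the
    earliest matching tweet is recorded as provenance.  Raises
    ``ValueError`` on mixed user ids.
    """
    tweet_hit: tuple[TweetRecord, MatchResult] | None = None
    for rec in sorted(tweets, key=lambda r: (r.created_at, r.tweet_id)):
        if rec.user_id != user.user_id:
            raise ValueError(
                f"record {rec.tweet_id} belongs to {rec.user_id}, not {user.user_id}"
            )
        m = match_tweet_text(rec.text, ps, mode=mode)
        if m is None:
            continue
        reported, _trigger = detect_reported_speech(
            rec.text, m.matched_span, speech_config
        )
        if reported:
            continue
        tweet_hit = (rec, m)
        break

    profile_hit = match_profile(user, ps, mode=mode)

    if tweet_hit and profile_hit:
        channel = Channel.BOTH
    elif tweet_hit:
        channel = Channel.TWEET
    elif profile_hit:
        channel = Channel.PROFILE
    else:
        return None

    return SelfReportEvidence(
        user_id=user.user_id,
        channel=channel,
        tweet_match=tweet_hit[1] if tweet_hit else None,
        tweet_id=tweet_hit[0].tweet_id if tweet_hit else None,
        profile_match=profile_hit,
    )
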