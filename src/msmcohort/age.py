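"""Self-reported age extraction from tweet text.

The pattern inventory is conservative and first-person anchored: "I'm
24 years old", "turned 30 today", "my 21st birthday".  Numbers followed
by percent signs or measurement units ("I'm 100% sure", "I'm 6 feet")
never count.  A user's age comes from their most recent tweet carrying
an age self-report; within a tweet, the largest mention wins (guards
against height/quantity numbers that slip past the unit guard).
Resolved ages below 13 are discarded — the platform's minimum age — and
ages are binned into the groups 13-24, 25-34, 35-44, 45-54, 55+.

Birth-year mentions ("born in 1995") are supported behind a config flag
and compute age against the tweet timestamp; off by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime

__all__ = [
    "AgeMention",
    "AgeReport",
    "AGE_GROUPS",
    "MIN_AGE",
    "extract_age_mentions",
    "resolve_user_age",
    "age_group_of",
]

MIN_AGE = 13
MAX_AGE = 130

#: (label, lo, hi) — inclusive bounds; hi of the open-ended top group is MAX_AGE
AGE_GROUPS: tuple[tuple[str, int, int], ...] = (
    ("13-24", 13, 24),
    ("25-34", 25, 34),
    ("35-44", 35, 44),
    ("45-54", 45, 54),
    ("55+", 55, MAX_AGE),
)


@dataclass(frozen=True)
class AgeMention:
    tweet_id: str
    value: int
    pattern_id: str
    created_at: datetime
    user_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.value <= MAX_AGE):
            raise ValueError(f"age value {self.value} outside [0, {MAX_AGE}]")


@dataclass(frozen=True)
class AgeReport:
    user_id: str
    age: int
    source_tweet_id: str
    age_group: str

    def __post_init__(self) -> None:
        if self.age < MIN_AGE:
            raise ValueError(f"age {self.age} below the {MIN_AGE}-year floor")


# a number immediately followed by a unit or percent is not an age
_UNIT_GUARD = (
    r"(?!\s*(?:%|percent\b|per\s*cent\b|ft\b|foot\b|feet\b|'|’|inch(?:es)?\b|"
    r"cm\b|kg\b|lbs?\b|pounds?\b|k\b|km\b|mi\b|miles?\b|dollars?\b|bucks?\b|"
    r"hours?\b|hrs?\b|minutes?\b|mins?\b|seconds?\b|days?\b|weeks?\b|months?\b|"
    r"followers?\b|likes?\b|times\b|million\b|billion\b))"
)

_NUM = r"(?<!\d)(?P<value>\d{1,3})(?!\d)"

_PATTERNS: tuple[tuple[str, re.Pattern], ...] = (
    (
        "first_person_am",
        re.compile(
            r"\bi\s*['’]?\s*a?m\s+(?:now\s+|only\s+|just\s+|officially\s+)?"
            + _NUM + _UNIT_GUARD
            + r"(?:\s*(?:-|–)?\s*years?[\s-]*old\b|\s*yo\b|\s*y/o\b)?",
            re.IGNORECASE,
        ),
    ),
    (
        "years_old",
        re.compile(
            _NUM + r"\s*(?:-|–)?\s*years?[\s-]*old\b",
            re.IGNORECASE,
        ),
    ),
    (
        "turned",
        re.compile(
            r"\bturn(?:ed|ing|s)?\s+" + _NUM + _UNIT_GUARD,
            re.IGNORECASE,
        ),
    ),
    (
        "ordinal_birthday",
        re.compile(
            r"\bmy\s+" + _NUM + r"(?:st|nd|rd|th)\s+b(?:irth)?day\b",
            re.IGNORECASE,
        ),
    ),
)

_BIRTH_YEAR_RE = re.compile(
    r"\b(?:i\s+was\s+born|born)\s+in\s+(?P<year>(?:19|20)\d{2})\b", re.IGNORECASE
)

_FIRST_PERSON_RE = re.compile(
    r"\b(?:i|me|my|mine|myself|i'm|i’m)\b", re.IGNORECASE
)


def extract_age_mentions(
    text: str,
    tweet_id: str = "",
    created_at: datetime | None = None,
    user_id: str = "",
    *,
    birth_year: bool = False,
) -> list[AgeMention]:
    """All first-person age mentions in a tweet, in text order.

    The bare ``years_old`` pattern requires a first-person pronoun
    somewhere in the text; the anchored patterns carry their own.
    Overlapping hits on the same number position are merged (first
    pattern in inventory order wins).
    """
    ts = created_at or datetime(1970, 1, 1)
    hits: list[tuple[int, str, int]] = []  # (position, pattern_id, value)
    claimed: set[int] = set()
    has_first_person = bool(_FIRST_PERSON_RE.search(text))
    for pattern_id, rx in _PATTERNS:
        if pattern_id == "years_old" and not has_first_person:
            continue
        for m in rx.finditer(text):
            pos = m.start("value")
            if pos in claimed:
                continue
            value = int(m.group("value"))
            if value > MAX_AGE:
                continue
            claimed.add(pos)
            hits.append((pos, pattern_id, value))
    if birth_year and ts.year > 1970:
        for m in _BIRTH_YEAR_RE.finditer(text):
            pos = m.start("year")
            if pos in claimed:
                continue
            age = ts.year - int(m.group("year"))
            if 0 <= age <= MAX_AGE:
                claimed.add(pos)
                hits.append((pos, "birth_year", age))
    hits.sort(key=lambda h: h[0])
    return [
        AgeMention(
            tweet_id=tweet_id, value=v, pattern_id=pid, created_at=ts, user_id=user_id
        )
        for pos, pid, v in hits
    ]


def age_group_of(age: int) -> str:
    """The unique bin containing ``age``; raises below the floor."""
    for label, lo, hi in AGE_GROUPS:
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} outside [{MIN_AGE}, {MAX_AGE}]")


def resolve_user_age(
    mentions: list[AgeMention], user_id: str
) -> AgeReport | None:
    """Resolve one user's age from all their mentions.

    The mention from the most recent tweet wins (ties: largest value);
    results below the 13-year floor yield None.
    """
    if not mentions:
        return None
    foreign = {m.user_id for m in mentions if m.user_id} - {user_id}
    if foreign:
        raise ValueError(f"mentions from other users: {sorted(foreign)}")
    best = max(mentions, key=lambda m: (m.created_at, m.value))
    # within the winning tweet, the largest value wins
    winners = [
        m for m in mentions
        if m.created_at == best.created_at and m.tweet_id == best.tweet_id
    ]
    value = max(m.value for m in winners)
    source = winners[0].tweet_id
    if value < MIN_AGE:
        return None
    return AgeReport(
        user_id=user_id,
        age=value,
        source_tweet_id=source,
        age_group=age_group_of(value),
    )
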