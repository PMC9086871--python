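"""Gazetteer-based resolution of users to US states and counties.

Free-text profile locations ("Los Angeles, CA", "philly", "Texas") are
matched against a gazetteer of states, counties, cities and informal
aliases.  Resolution is precision-first: an ambiguous city name without
a state hint ("Springfield") resolves to nothing rather than guessing,
and non-US or unrecognizable strings (emoji flags, "Mars") resolve to
nothing — unresolvable is a value, not an error.

Structured place metadata on a tweet, when present and US, takes
priority over the free-text profile location.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

from .records import Place, UserRecord

__all__ = [
    "Gazetteer",
    "GeoResolution",
    "GeoSource",
    "GazetteerError",
    "load_gazetteer",
    "load_default_gazetteer",
    "resolve_location",
]


class GazetteerError(ValueError):
    """Invalid gazetteer content (unknown kind, dangling reference, dupes)."""


class GeoSource(str, Enum):
    PLACE_METADATA = "place_metadata"
    PROFILE_LOCATION = "profile_location"


@dataclass(frozen=True)
class GeoResolution:
    user_id: str
    state: str | None = None  # USPS code
    county: str | None = None  # canonical county name
    source: GeoSource = GeoSource.PROFILE_LOCATION

    def __post_init__(self) -> None:
        if self.county is not None and self.state is None:
            raise ValueError("county-level resolution requires a state")


@dataclass
class Gazetteer:
    """Lookup tables keyed by normalized (lowercased, squeezed) names."""

    states_by_name: dict[str, str] = field(default_factory=dict)  # name -> USPS
    states_by_code: dict[str, str] = field(default_factory=dict)  # USPS -> name
    counties: set[tuple[str, str]] = field(default_factory=set)  # (county, state)
    counties_by_name: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    cities: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    # city -> [(city display, county, state)]
    aliases: dict[str, tuple[str | None, str]] = field(default_factory=dict)
    # alias -> (county or None, state)

    @property
    def n_states(self) -> int:
        return len(self.states_by_code)

    def has_county(self, county: str, state: str) -> bool:
        return (county, state) in self.counties


_WS_RE = re.compile(r"\s+")


def _norm(s: str) -> str:
    return _WS_RE.sub(" ", s.strip().lower())


def _canonical_county(name: str) -> str:
    """Counties are stored under their canonical printed name."""
    return _WS_RE.sub(" ", name.strip())


def load_gazetteer(path: str | Path) -> Gazetteer:
    """Load and validate a TSV gazetteer.

    Columns: ``kind`` (state|county|city|alias), ``name``, ``state``,
    ``county``.  Counties must reference a loaded state; cities must
    reference a loaded (county, state); alias targets must exist.
    Duplicate (kind, name, state) rows are rejected.  Errors carry the
    offending line number.
    """
    g = Gazetteer()
    rows: list[tuple[int, dict]] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        for i, row in enumerate(reader, start=2):
            rows.append((i, row))

    seen: set[tuple[str, str, str]] = set()

    def check_dup(lineno: int, kind: str, name: str, state: str) -> None:
        key = (kind, _norm(name), state)
        if key in seen:
            raise GazetteerError(f"line {lineno}: duplicate {kind} row {name!r}, {state}")
        seen.add(key)

    # two passes: states first so references can be validated
    for lineno, row in rows:
        kind = (row.get("kind") or "").strip()
        if kind == "state":
            name, code = row["name"].strip(), row["state"].strip().upper()
            check_dup(lineno, kind, name, code)
            g.states_by_name[_norm(name)] = code
            g.states_by_code[code] = name
        elif kind not in {"county", "city", "alias"}:
            raise GazetteerError(f"line {lineno}: unknown kind {kind!r}")

    for lineno, row in rows:
        kind = row["kind"].strip()
        name = (row.get("name") or "").strip()
        state = (row.get("state") or "").strip().upper()
        county = _canonical_county(row.get("county") or "")
        if kind == "state":
            continue
        if state and state not in g.states_by_code:
            raise GazetteerError(f"line {lineno}: unknown state {state!r}")
        if kind == "county":
            check_dup(lineno, kind, name, state)
            if not state:
                raise GazetteerError(f"line {lineno}: county {name!r} lacks a state")
            canon = _canonical_county(name)
            g.counties.add((canon, state))
            g.counties_by_name.setdefault(_norm(canon), []).append((canon, state))
        elif kind == "city":
            check_dup(lineno, kind, name, state)
            if not state or not county:
                raise GazetteerError(f"line {lineno}: city {name!r} lacks state/county")
            if (county, state) not in g.counties:
                raise GazetteerError(
                    f"line {lineno}: city {name!r} references unknown county "
                    f"({county!r}, {state})"
                )
            g.cities.setdefault(_norm(name), []).append((name, county, state))
        elif kind == "alias":
            check_dup(lineno, kind, name, state)
            if not state:
                raise GazetteerError(f"line {lineno}: alias {name!r} lacks a target state")
            if county:
                if (county, state) not in g.counties:
                    raise GazetteerError(
                        f"line {lineno}: alias {name!r} references unknown county "
                        f"({county!r}, {state})"
                    )
                g.aliases[_norm(name)] = (county, state)
            else:
                g.aliases[_norm(name)] = (None, state)
    return g


def load_default_gazetteer() -> Gazetteer:
    """The gazetteer shipped as package data (50 states + DC, major
    metros, EHE counties, informal aliases)."""
    with resources.as_file(
        resources.files("msmcohort").joinpath("data/gazetteer.tsv")
    ) as p:
        return load_gazetteer(p)


_SPLIT_RE = re.compile(r"[,/|•·]+")
_STRIP_RE = re.compile(r"^[\s\W_]+|[\s\W_]+$")


def _tokens(text: str) -> list[str]:
    out = []
    for part in _SPLIT_RE.split(text):
        part = _STRIP_RE.sub("", part)
        if part:
            out.append(_norm(part))
    return out


def _state_of_token(tok: str, g: Gazetteer) -> str | None:
    if tok.upper() in g.states_by_code:
        return tok.upper()
    return g.states_by_name.get(tok)


def _resolve_text(text: str, g: Gazetteer) -> tuple[str | None, str | None]:
    toks = _tokens(text)
    if not toks:
        return None, None

    # The last state-matching token serves as the disambiguation hint
    # ("City, State" convention); that token itself is then excluded from
    # city/county lookup so that a bare state name ("New York") resolves
    # to the state, not the homonymous city.
    hint: str | None = None
    hint_tok: str | None = None
    for tok in toks:
        st = _state_of_token(tok, g)
        if st is not None:
            hint, hint_tok = st, tok

    # cities (and informal aliases) first: they give the finest resolution
    for tok in toks:
        if tok == hint_tok:
            continue
        if tok in g.aliases:
            county, state = g.aliases[tok]
            if hint is None or hint == state:
                return state, county
        cands = g.cities.get(tok, [])
        if hint is not None:
            cands = [c for c in cands if c[2] == hint]
        if len(cands) == 1:
            _, county, state = cands[0]
            return state, county
        # ambiguous city without a usable hint: precision-first, keep looking

    for tok in toks:
        if tok == hint_tok:
            continue
        # accept both "Los Angeles County" and bare "Los Angeles" county refs
        for key in (tok, tok + " county"):
            cands = g.counties_by_name.get(key, [])
            if hint is not None:
                cands = [c for c in cands if c[1] == hint]
            if len(cands) == 1:
                county, state = cands[0]
                return state, county

    if hint is not None:
        # DC is both a state-level and a county-level unit
        if hint == "DC" and ("District of Columbia", "DC") in g.counties:
            return "DC", "District of Columbia"
        return hint, None
    return None, None


def resolve_location(
    user: UserRecord, g: Gazetteer, place: Place | None = None
) -> GeoResolution:
    """Resolve a user to a US state and, where possible, a county.

    Structured place metadata (when present and US) takes priority over
    the free-text profile location.  Matching is case- and
    whitespace-insensitive; every emitted (county, state) pair exists in
    the gazetteer.
    """
    if place is not None and place.country_code.upper() == "US" and place.full_name:
        state, county = _resolve_text(place.full_name, g)
        if state is not None:
            return GeoResolution(
                user_id=user.user_id,
                state=state,
                county=county,
                source=GeoSource.PLACE_METADATA,
            )
    state, county = _resolve_text(user.user_location or "", g)
    return GeoResolution(
        user_id=user.user_id,
        state=state,
        county=county,
        source=GeoSource.PROFILE_LOCATION,
    )
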