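"""Cohort assembly and demographic reporting.

Users matched through the tweet and profile channels are deduplicated
into a single cohort (evidence ``both`` for the intersection), then
summarized: per-state counts, a county table restricted to counties
with at least ``min_count`` users, the age distribution over the five
age groups, and overlap with HIV-priority jurisdiction lists (the ten
states with the most new HIV diagnoses; the Ending the HIV Epidemic
initiative's priority counties and states).

All percentages use half-up rounding (not banker's): 1 decimal place
for shares, 2 for precision.  Denominators are nested — county shares
are taken over county-resolved users, state shares over state-resolved
users — so each table's counts sum to its own denominator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd

from .age import AGE_GROUPS, AgeReport
from .geo import Gazetteer, GeoResolution
from .patterns import Channel

__all__ = [
    "CohortUser",
    "JurisdictionList",
    "DemographicSummary",
    "build_cohort",
    "pct",
    "state_counts",
    "county_table",
    "age_table",
    "age_stats",
    "jurisdiction_overlap",
    "load_jurisdiction_list",
    "load_default_jurisdictions",
]


@dataclass
class CohortUser:
    user_id: str
    evidence: Channel
    geo: GeoResolution | None = None
    age: AgeReport | None = None


@dataclass(frozen=True)
class JurisdictionList:
    """A named reference list of states and/or counties."""

    name: str
    states: frozenset[str]
    counties: frozenset[tuple[str, str]]  # (county, state)

    def __post_init__(self) -> None:
        if not self.states and not self.counties:
            raise ValueError(f"jurisdiction list {self.name!r} is empty")

    def contains(self, user: CohortUser) -> bool:
        """A user counts if their county is listed OR their state is."""
        if user.geo is None:
            return False
        if user.geo.county is not None and user.geo.state is not None:
            if (user.geo.county, user.geo.state) in self.counties:
                return True
        return user.geo.state in self.states


def build_cohort(
    tweet_matched: set[str], profile_matched: set[str]
) -> dict[str, CohortUser]:
    """Deduplicated union of the two channel searches.

    Users found by both searches carry evidence ``both`` and are
    counted once.
    """
    cohort: dict[str, CohortUser] = {}
    for uid in sorted(tweet_matched | profile_matched):
        if uid in tweet_matched and uid in profile_matched:
            ev = Channel.BOTH
        elif uid in tweet_matched:
            ev = Channel.TWEET
        else:
            ev = Channel.PROFILE
        cohort[uid] = CohortUser(user_id=uid, evidence=ev)
    return cohort


def pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` with half-up rounding.

    Exact on terminating decimals: ``pct(417, 500, 1) == 83.4`` and
    ``pct(430, 500, 0) == 86``.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must lie in [0, denominator]")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


def _state_resolved(cohort: dict[str, CohortUser]) -> list[CohortUser]:
    return [u for u in cohort.values() if u.geo is not None and u.geo.state]


def _county_resolved(cohort: dict[str, CohortUser]) -> list[CohortUser]:
    return [
        u
        for u in cohort.values()
        if u.geo is not None and u.geo.state and u.geo.county
    ]


def state_counts(cohort: dict[str, CohortUser]) -> pd.Series:
    """Users per state, descending; sums to the state-resolved count."""
    counts: dict[str, int] = {}
    for u in _state_resolved(cohort):
        counts[u.geo.state] = counts.get(u.geo.state, 0) + 1
    s = pd.Series(counts, dtype=int, name="users")
    return s.sort_values(ascending=False, kind="stable")


def county_table(cohort: dict[str, CohortUser], min_count: int = 100) -> pd.DataFrame:
    """Counties with at least ``min_count`` users.

    Shares are over the county-resolved denominator, not cohort size.
    """
    resolved = _county_resolved(cohort)
    denom = len(resolved)
    counts: dict[tuple[str, str], int] = {}
    for u in resolved:
        key = (u.geo.county, u.geo.state)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "county": county,
            "state": state,
            "count": n,
            "share_pct": pct(n, denom, 1),
        }
        for (county, state), n in counts.items()
        if n >= min_count
    ]
    df = pd.DataFrame(rows, columns=["county", "state", "count", "share_pct"])
    return df.sort_values(
        ["count", "county"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def age_table(cohort: dict[str, CohortUser]) -> pd.DataFrame:
    """Age-group distribution over users with resolved ages."""
    aged = [u for u in cohort.values() if u.age is not None]
    denom = len(aged)
    rows = []
    for label, _lo, _hi in AGE_GROUPS:
        n = sum(1 for u in aged if u.age.age_group == label)
        rows.append(
            {
                "age_group": label,
                "count": n,
                "share_pct": pct(n, denom, 1) if denom else float("nan"),
            }
        )
    df = pd.DataFrame(rows, columns=["age_group", "count", "share_pct"])
    df.attrs["denominator"] = denom
    return df


def age_stats(cohort: dict[str, CohortUser]) -> dict[str, float]:
    """Mean / SD / median of resolved ages, to 1 decimal."""
    ages = [u.age.age for u in cohort.values() if u.age is not None]
    if not ages:
        return {}
    s = pd.Series(ages, dtype=float)
    return {
        "mean": round(float(s.mean()), 1),
        "sd": round(float(s.std(ddof=1)), 1) if len(ages) > 1 else 0.0,
        "median": round(float(s.median()), 1),
        "n": len(ages),
    }


def jurisdiction_overlap(
    cohort: dict[str, CohortUser],
    jl: JurisdictionList,
    denominator_rule: str = "state_resolved",
) -> dict:
    """Fraction of geolocated users inside a priority jurisdiction list.

    ``denominator_rule`` selects the nested denominator: all
    state-resolved users, or only county-resolved users.
    """
    if denominator_rule == "state_resolved":
        denom_users = _state_resolved(cohort)
    elif denominator_rule == "county_resolved":
        denom_users = _county_resolved(cohort)
    else:
        raise ValueError(f"unknown denominator rule {denominator_rule!r}")
    if not denom_users:
        raise ValueError("empty denominator: no geolocated users")
    numer = sum(1 for u in denom_users if jl.contains(u))
    return {
        "list": jl.name,
        "numerator": numer,
        "denominator": len(denom_users),
        "share_pct": pct(numer, len(denom_users), 1),
    }


@dataclass
class DemographicSummary:
    n_cohort: int
    n_state_resolved: int
    n_county_resolved: int
    n_aged: int
    state_counts: pd.Series
    county_table: pd.DataFrame
    age_table: pd.DataFrame
    age_stats: dict
    overlaps: list[dict] = field(default_factory=list)


def summarize(
    cohort: dict[str, CohortUser],
    jurisdictions: list[tuple[JurisdictionList, str]] | None = None,
    min_county_count: int = 100,
) -> DemographicSummary:
    """One-stop demographic summary of a cohort.

    ``jurisdictions`` pairs each list with its denominator rule.
    """
    overlaps = []
    for jl, rule in jurisdictions or []:
        overlaps.append(jurisdiction_overlap(cohort, jl, rule))
    return DemographicSummary(
        n_cohort=len(cohort),
        n_state_resolved=len(_state_resolved(cohort)),
        n_county_resolved=len(_county_resolved(cohort)),
        n_aged=sum(1 for u in cohort.values() if u.age is not None),
        state_counts=state_counts(cohort),
        county_table=county_table(cohort, min_county_count),
        age_table=age_table(cohort),
        age_stats=age_stats(cohort),
        overlaps=overlaps,
    )


def load_jurisdiction_list(
    path: str | Path, name: str, gazetteer: Gazetteer | None = None
) -> JurisdictionList:
    """Load a jurisdiction list from CSV (columns: kind, name, state).

    ``kind`` is ``state`` or ``county``.  With a gazetteer supplied,
    every entry is checked for referential validity.
    """
    states: set[str] = set()
    counties: set[tuple[str, str]] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(ln for ln in fh if not ln.startswith("#"))
        for i, row in enumerate(reader, start=2):
            kind = row["kind"].strip()
            state = row["state"].strip().upper()
            if kind == "state":
                states.add(state)
                if gazetteer and state not in gazetteer.states_by_code:
                    raise ValueError(f"{path}:{i}: unknown state {state!r}")
            elif kind == "county":
                county = row["name"].strip()
                counties.add((county, state))
                if gazetteer and not gazetteer.has_county(county, state):
                    raise ValueError(
                        f"{path}:{i}: county ({county!r}, {state}) not in gazetteer"
                    )
            else:
                raise ValueError(f"{path}:{i}: unknown kind {kind!r}")
    return JurisdictionList(
        name=name, states=frozenset(states), counties=frozenset(counties)
    )


def load_default_jurisdictions(
    gazetteer: Gazetteer | None = None,
) -> dict[str, JurisdictionList]:
    """The two shipped reference lists: ``top10_hiv_states`` and
    ``ehe_priority``."""
    out = {}
    base = resources.files("msmcohort").joinpath("data/jurisdictions")
    for stem in ("top10_hiv_states", "ehe_priority"):
        with resources.as_file(base.joinpath(stem + ".csv")) as p:
            out[stem] = load_jurisdiction_list(p, stem, gazetteer)
    return out
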