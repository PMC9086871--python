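"""Labeled synthetic tweet-stream generator.

Emulates the statistical structure of a keyword-filtered Twitter stream
as seen by the self-report pipeline: a mixture of genuine first-person
self-reports (tweet channel, profile channel, or both), third-person
mentions (memorials, news-style items), trans/nonbinary profile decoys,
retweets, quoted/reported speech, free-text profile locations drawn
from the gazetteer, and first-person age mentions — together with a
ground-truth table per user, so precision, recall and geolocation/age
accuracy can be measured exactly.

The default rates describe a matched population with roughly 0.85
precision and a 60/40 tweet/profile channel mix — the operating point
a high-precision handwritten-pattern pipeline realistically achieves on
such a stream.  Genuine self-reports are drawn from the matcher's own
template space, so a generated true positive always matches the default
pattern set; generated retweets always carry the retweet convention; and
generated reported-speech items always place the would-be match inside a
quoted or attributed region.  The generator and the pipeline are
co-tested through these invariants.

Output is byte-deterministic under a fixed seed.  The v1 (nested)
dialect is written by default, with a flag for v2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortUser
from .geo import Gazetteer, load_default_gazetteer

__all__ = [
    "CorpusSpec",
    "DEFAULT_STATE_WEIGHTS",
    "DEFAULT_AGE_DISTRIBUTION",
    "generate_corpus",
    "write_corpus",
    "expected_precision",
    "score_pipeline",
]

#: Rough state mix of a US-wide stream: the big coastal and sun-belt
#: states dominate.  Restricted to states with city coverage in the
#: shipped gazetteer; normalized at draw time.
DEFAULT_STATE_WEIGHTS: dict[str, float] = {
    "CA": 0.16, "NY": 0.12, "TX": 0.11, "FL": 0.09, "IL": 0.06,
    "PA": 0.05, "OH": 0.045, "GA": 0.045, "WA": 0.035, "MA": 0.03,
    "NC": 0.03, "AZ": 0.025, "MI": 0.025, "NJ": 0.025, "TN": 0.02,
    "NV": 0.02, "OR": 0.02, "MD": 0.02, "WI": 0.015, "IN": 0.015,
    "LA": 0.015, "NM": 0.01, "MO": 0.01, "DC": 0.02,
}

#: Five-group age mix of users young enough to self-report ages online.
DEFAULT_AGE_DISTRIBUTION: dict[str, float] = {
    "13-24": 0.341,
    "25-34": 0.344,
    "35-44": 0.147,
    "45-54": 0.094,
    "55+": 0.074,
}

_AGE_BIN_RANGES = {
    "13-24": (13, 24),
    "25-34": (25, 34),
    "35-44": (35, 44),
    "45-54": (45, 54),
    "55+": (55, 84),
}


@dataclass
class CorpusSpec:
    """Generator configuration; the defaults are the study conditions."""

    n_users: int = 10043
    tp_tweet_rate: float = 0.37      # tweet-channel true positives (incl. both)
    tp_profile_rate: float = 0.25    # profile-channel true positives (incl. both)
    tp_both_rate: float = 0.03       # overlap of the two channels
    fp_thirdperson_rate: float = 0.07
    fp_transnb_rate: float = 0.035
    retweet_rate: float = 0.30       # chance a user also emits a retweet
    reported_speech_rate: float = 0.05  # chance of a quoted/attributed decoy
    geo_coverage: float = 0.876
    county_coverage: float = 0.712   # among geolocated users
    age_coverage: float = 0.476
    state_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_WEIGHTS)
    )
    age_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTION)
    )
    seed: int = 0
    dialect: str = "v1"

    def __post_init__(self) -> None:
        rates = {
            "tp_tweet_rate": self.tp_tweet_rate,
            "tp_profile_rate": self.tp_profile_rate,
            "tp_both_rate": self.tp_both_rate,
            "fp_thirdperson_rate": self.fp_thirdperson_rate,
            "fp_transnb_rate": self.fp_transnb_rate,
            "retweet_rate": self.retweet_rate,
            "reported_speech_rate": self.reported_speech_rate,
            "geo_coverage": self.geo_coverage,
            "county_coverage": self.county_coverage,
            "age_coverage": self.age_coverage,
        }
        for name, r in rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name}={r} outside [0, 1]")
        if self.tp_both_rate > min(self.tp_tweet_rate, self.tp_profile_rate):
            raise ValueError("tp_both_rate exceeds a channel rate")
        if self._matched_mass() > 1.0 + 1e-9:
            raise ValueError("role rates sum to more than 1")
        if self.dialect not in ("v1", "v2"):
            raise ValueError(f"dialect must be v1 or v2, got {self.dialect!r}")
        for dist_name in ("state_weights", "age_distribution"):
            dist = getattr(self, dist_name)
            if not dist or any(w < 0 for w in dist.values()) or sum(dist.values()) <= 0:
                raise ValueError(f"{dist_name} must be non-negative and non-empty")

    def _matched_mass(self) -> float:
        return (
            self.tp_tweet_rate
            + self.tp_profile_rate
            - self.tp_both_rate
            + self.fp_thirdperson_rate
            + self.fp_transnb_rate
        )


def expected_precision(spec: CorpusSpec) -> float:
    """Analytic precision of a perfect matcher on this mixture.

    Generated true positives always match and generated decoys always
    match (in default mode), so precision is the TP share of the
    matched mass.
    """
    tp = spec.tp_tweet_rate + spec.tp_profile_rate - spec.tp_both_rate
    matched = spec._matched_mass()
    if matched == 0:
        raise ValueError("no matched users under this spec")
    return tp / matched


# --- surface realization pools ------------------------------------------

_IDENTITY = ["gay", "bi", "bisexual"]
_PERSON_SG = ["man", "guy", "dude"]
_PERSON_PL = ["men", "guys", "dudes"]

_TP_TWEETS = [
    "I'm a {i} {p} and it took me years to say that out loud.",
    "as a {i} {p} we really do deserve better healthcare access.",
    "{i} {pl} like me just want some decent representation on tv.",
    "being a {i} {p} in this town is a whole adventure, honestly.",
    "I am a {i} {p} and I will not apologize for it.",
]

_FP_THIRDPERSON_TWEETS = [
    "Today we remember {name}, whose life was cut short because of his "
    "identity as a {i} {p}.",
    "He finally came out as a {i} {p} last year and his family embraced him. "
    "We love to see it.",
    "Rest in power {name}. He lived proudly as a {i} {p} and we will not "
    "forget him.",
]

_REPORTED_SPEECH_TWEETS = [
    '"I am a {i} {p}, and I vote," he said at the rally.',
    '"As a {i} {p} I worry about access to care," he told the paper.',
    "I am a {i} {p} and nothing will change that, he said.",
]

_RT_TWEETS = [
    "RT @{h}: I'm a {i} {p} and it took me years to say that out loud.",
    "RT @{h}: as a {i} {p} we really do deserve better healthcare access.",
]

_BACKGROUND_TWEETS = [
    "the farmers market haul today was unreal, best tomatoes of the summer",
    "can this bus ever run on time, asking for a friend",
    "new episode tonight and the group chat is already losing it",
    "rain again. the garden is happy even if nobody else is",
    "finally finished that book everyone kept recommending. worth it",
    "three coffees deep and the spreadsheet is still winning",
]

_AGE_TWEETS = [
    "I'm {n} years old and my back already files complaints.",
    "turned {n} today and the candles nearly set off the alarm!!",
    "my {ord} birthday was honestly the best one yet.",
    "I am {n} and I still cannot parallel park.",
]

_TP_PROFILES = [
    "A proud {adj} {i} {p}. {hobby} lover.",
    "{i} {p}, {hobby} enthusiast, occasional poet.",
    "just a {i} {p} from {region} who loves {hobby}.",
]

_FP_TRANSNB_PROFILES = [
    "{age_dec}+ {i} trans {p}, writer, film and {hobby} lover. "
    "he/him or they/them.",
    "nonbinary {i} {p}. {hobby} nerd. they/them.",
    "proud trans {i} {p}. {hobby} and tea. he/they.",
]

_NEUTRAL_PROFILES = [
    "{hobby} enthusiast. perpetually caffeinated.",
    "posts about {hobby} and not much else. he/him.",
    "{region} born and raised. {hobby} on weekends.",
    "dad jokes, {hobby}, and long walks.",
]

_ADJ = ["black", "proud", "happy", "quiet", "loud"]
_HOBBY = ["food", "film", "soccer", "synthwave", "cycling", "chess"]
_REGION = ["the midwest", "the coast", "down south", "up north"]
_NAMES = ["Marcus", "Daniel", "Alex", "Jordan", "Sam", "Chris"]
_HANDLES = ["newsfeed1", "dailywire22", "friendofmine", "someguy88"]

_NO_GEO_STRINGS = ["", "Mars", "the moon", "\U0001F308\U0001F30D", "everywhere and nowhere"]

_BASE_TIME = datetime(2020, 9, 1, 12, 0, 0, tzinfo=timezone.utc)


def _ordinal(n: int) -> str:
    if 10 <= n % 100 <= 20:
        return f"{n}th"
    return f"{n}{'st' if n % 10 == 1 else 'nd' if n % 10 == 2 else 'rd' if n % 10 == 3 else 'th'}"


def _v1_time(ts: datetime) -> str:
    return ts.strftime("%a %b %d %H:%M:%S +0000 %Y")


def _pick(rng: np.random.Generator, pool: list[str]) -> str:
    return pool[int(rng.integers(len(pool)))]


def _cities_by_state(g: Gazetteer) -> dict[str, list[tuple[str, str]]]:
    out: dict[str, list[tuple[str, str]]] = {}
    for cands in g.cities.values():
        for display, county, state in cands:
            out.setdefault(state, []).append((display, county))
    for v in out.values():
        v.sort()
    return out


def generate_corpus(
    spec: CorpusSpec, gazetteer: Gazetteer | None = None
) -> tuple[list[dict], pd.DataFrame]:
    """Generate raw tweet objects plus a per-user ground-truth table.

    Returns ``(records, truth)`` where records are dialect-formatted
    JSON-serializable dicts in emission order, and truth has one row per
    user: ``user_id, is_true_positive, channel, true_state, true_county,
    true_age``.
    """
    g = gazetteer if gazetteer is not None else load_default_gazetteer()
    cities = _cities_by_state(g)
    rng = np.random.default_rng(spec.seed)

    states = sorted(spec.state_weights)
    sw = np.array([spec.state_weights[s] for s in states], dtype=float)
    sw = sw / sw.sum()
    bins = sorted(spec.age_distribution)
    aw = np.array([spec.age_distribution[b] for b in bins], dtype=float)
    aw = aw / aw.sum()

    roles = ["tp_both", "tp_tweet", "tp_profile", "fp_thirdperson", "fp_transnb"]
    probs = np.array(
        [
            spec.tp_both_rate,
            spec.tp_tweet_rate - spec.tp_both_rate,
            spec.tp_profile_rate - spec.tp_both_rate,
            spec.fp_thirdperson_rate,
            spec.fp_transnb_rate,
        ]
    )
    probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
    roles.append("negative")

    records: list[dict] = []
    truth_rows: list[dict] = []
    tweet_seq = 0

    def emit(user: dict, text: str, ts: datetime) -> None:
        nonlocal tweet_seq
        tweet_seq += 1
        tid = f"{900000000 + tweet_seq:012d}"
        if spec.dialect == "v1":
            records.append(
                {
                    "id_str": tid,
                    "created_at": _v1_time(ts),
                    "text": text,
                    "user": {
                        "id_str": user["user_id"],
                        "name": user["name"],
                        "description": user["description"],
                        "location": user["location"],
                    },
                }
            )
        else:
            rec = {
                "id": tid,
                "created_at": ts.isoformat().replace("+00:00", "Z"),
                "text": text,
                "author_id": user["user_id"],
                "author_name": user["name"],
                "author_description": user["description"],
                "author_location": user["location"],
            }
            if text.startswith("RT @"):
                rec["referenced_tweets"] = [{"type": "retweeted", "id": "0"}]
            records.append(rec)

    for u in range(spec.n_users):
        uid = f"u{u:07d}"
        role = roles[int(rng.choice(len(roles), p=probs))]
        identity = _pick(rng, _IDENTITY)
        person = _pick(rng, _PERSON_SG)
        person_pl = _pick(rng, _PERSON_PL)

        # --- geolocation -------------------------------------------------
        true_state: str | None = None
        true_county: str | None = None
        if rng.random() < spec.geo_coverage:
            true_state = states[int(rng.choice(len(states), p=sw))]
            want_county = rng.random() < spec.county_coverage
            if true_state == "DC":
                # DC is a single county-equivalent unit
                true_county = "District of Columbia"
                location = "Washington, DC"
            elif want_county and cities.get(true_state):
                city, county = cities[true_state][
                    int(rng.integers(len(cities[true_state])))
                ]
                true_county = county
                location = f"{city}, {true_state}"
            else:
                location = (
                    g.states_by_code[true_state]
                    if rng.random() < 0.5
                    else true_state
                )
        else:
            location = _pick(rng, _NO_GEO_STRINGS)

        # --- profile -----------------------------------------------------
        hobby = _pick(rng, _HOBBY)
        if role in ("tp_profile", "tp_both"):
            description = _pick(rng, _TP_PROFILES).format(
                adj=_pick(rng, _ADJ), i=identity, p=person,
                hobby=hobby, region=_pick(rng, _REGION),
            )
        elif role == "fp_transnb":
            description = _pick(rng, _FP_TRANSNB_PROFILES).format(
                age_dec=int(rng.integers(3, 7)) * 10, i=identity, p=person,
                hobby=hobby,
            )
        else:
            description = _pick(rng, _NEUTRAL_PROFILES).format(
                hobby=hobby, region=_pick(rng, _REGION)
            )

        user = {
            "user_id": uid,
            "name": f"{_pick(rng, _NAMES)} {chr(65 + u % 26)}.",
            "description": description,
            "location": location,
        }

        t0 = _BASE_TIME + timedelta(minutes=int(rng.integers(0, 200_000)))
        step = timedelta(minutes=int(rng.integers(1, 240)))
        n_bg = int(rng.integers(1, 4))
        ts = t0
        for _ in range(n_bg):
            emit(user, _pick(rng, _BACKGROUND_TWEETS), ts)
            ts += step

        if role in ("tp_tweet", "tp_both"):
            text = _pick(rng, _TP_TWEETS).format(i=identity, p=person, pl=person_pl)
            emit(user, text, ts)
            ts += step
        elif role == "fp_thirdperson":
            text = _pick(rng, _FP_THIRDPERSON_TWEETS).format(
                name=_pick(rng, _NAMES), i=identity, p=person
            )
            emit(user, text, ts)
            ts += step

        if rng.random() < spec.reported_speech_rate:
            emit(
                user,
                _pick(rng, _REPORTED_SPEECH_TWEETS).format(i=identity, p=person),
                ts,
            )
            ts += step

        if rng.random() < spec.retweet_rate:
            emit(
                user,
                _pick(rng, _RT_TWEETS).format(
                    h=_pick(rng, _HANDLES), i=identity, p=person
                ),
                ts,
            )
            ts += step

        # --- age ---------------------------------------------------------
        true_age: int | None = None
        if rng.random() < spec.age_coverage:
            bin_label = bins[int(rng.choice(len(bins), p=aw))]
            lo, hi = _AGE_BIN_RANGES[bin_label]
            true_age = int(rng.integers(lo, hi + 1))
            tmpl = _pick(rng, _AGE_TWEETS)
            emit(
                user,
                tmpl.format(n=true_age, ord=_ordinal(true_age)),
                ts,
            )
            ts += step

        channel = {
            "tp_tweet": "tweet",
            "tp_profile": "profile",
            "tp_both": "both",
            "fp_thirdperson": "tweet",
            "fp_transnb": "profile",
            "negative": "",
        }[role]
        truth_rows.append(
            {
                "user_id": uid,
                "role": role,
                "is_true_positive": role in ("tp_tweet", "tp_profile", "tp_both"),
                "should_match": role != "negative",
                "channel": channel,
                "true_state": true_state or "",
                "true_county": true_county or "",
                "true_age": true_age if true_age is not None else "",
            }
        )

    truth = pd.DataFrame(truth_rows)
    return records, truth


def write_corpus(
    spec: CorpusSpec,
    out_corpus: str | Path,
    out_truth: str | Path,
    gazetteer: Gazetteer | None = None,
) -> tuple[int, int]:
    """Generate and write JSON Lines corpus + CSV truth; byte-
    deterministic under a fixed seed.  Returns (n_records, n_users)."""
    records, truth = generate_corpus(spec, gazetteer)
    with Path(out_corpus).open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")
    truth.to_csv(out_truth, index=False, lineterminator="\n")
    return len(records), len(truth)


def score_pipeline(
    cohort: dict[str, CohortUser], truth: pd.DataFrame
) -> dict[str, float | None]:
    """Score a pipeline run against generator ground truth.

    precision = TP / (TP + FP) over cohort users; recall over truth's
    true-positive users; exact-match accuracy for state, county and age
    over cohort users whose truth value is set.  Precision is absent
    (None) for an empty cohort; a cohort user missing from truth is a
    contract error.
    """
    t = truth.set_index("user_id")
    unknown = [uid for uid in cohort if uid not in t.index]
    if unknown:
        raise ValueError(f"cohort users absent from truth: {unknown[:5]}")

    n_pos = int(t["is_true_positive"].sum())
    tp = sum(1 for uid in cohort if bool(t.at[uid, "is_true_positive"]))
    fp = len(cohort) - tp

    def _acc(col: str, getter) -> float | None:
        pairs = []
        for uid, cu in cohort.items():
            true_val = t.at[uid, col]
            if true_val == "" or pd.isna(true_val):
                continue
            pairs.append((str(true_val), getter(cu)))
        if not pairs:
            return None
        return sum(1 for tv, pv in pairs if pv is not None and str(pv) == tv) / len(pairs)

    return {
        "n_cohort": len(cohort),
        "n_true_positive": n_pos,
        "precision": tp / (tp + fp) if cohort else None,
        "recall": tp / n_pos if n_pos else None,
        "state_accuracy": _acc("true_state", lambda cu: cu.geo.state if cu.geo else None),
        "county_accuracy": _acc(
            "true_county", lambda cu: cu.geo.county if cu.geo else None
        ),
        "age_accuracy": _acc(
            "true_age",
            lambda cu: str(cu.age.age) if cu.age is not None else None,
        ),
    }
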