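"""End-to-end pipeline: stream in, cohort out.

Order of operations mirrors the identification pipeline: normalize the
stream, drop retweets, match tweet text and profile metadata against
the self-report grammar (suppressing matches that sit in reported
speech), deduplicate users across the two channels, then attach
geolocation and self-reported age to each cohort member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .age import extract_age_mentions, resolve_user_age
from .cohort import CohortUser
from .geo import Gazetteer, load_default_gazetteer, resolve_location
from .noise import FilterDecision, ReportedSpeechConfig, filter_stream
from .patterns import (
    Channel,
    PatternSet,
    SelfReportEvidence,
    classify_user,
    compile_pattern_set,
)
from .records import TweetRecord, consolidate_users

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    cohort: dict[str, CohortUser]
    evidences: dict[str, SelfReportEvidence]
    decisions: list[FilterDecision]
    n_input_records: int = 0
    n_retained_records: int = 0


def run_pipeline(
    records: list[TweetRecord],
    pattern_set: PatternSet | None = None,
    gazetteer: Gazetteer | None = None,
    speech_config: ReportedSpeechConfig | None = None,
    mode: str = "default",
    *,
    birth_year_ages: bool = False,
) -> PipelineResult:
    """Run the full identification pipeline over normalized records."""
    ps = pattern_set if pattern_set is not None else compile_pattern_set()
    g = gazetteer if gazetteer is not None else load_default_gazetteer()

    retained, decisions = filter_stream(records)

    # profile metadata may come from any record, including retweets
    users = consolidate_users(records)

    by_user: dict[str, list[TweetRecord]] = {}
    for rec in retained:
        by_user.setdefault(rec.user_id, []).append(rec)

    cohort: dict[str, CohortUser] = {}
    evidences: dict[str, SelfReportEvidence] = {}
    for uid in sorted(users):
        user = users[uid]
        ev = classify_user(
            by_user.get(uid, []), user, ps, speech_config, mode=mode
        )
        if ev is None:
            continue
        evidences[uid] = ev

        geo = resolve_location(user, g, place=_latest_place(by_user.get(uid, [])))

        mentions = []
        for rec in by_user.get(uid, []):
            mentions.extend(
                extract_age_mentions(
                    rec.text,
                    tweet_id=rec.tweet_id,
                    created_at=rec.created_at,
                    user_id=uid,
                    birth_year=birth_year_ages,
                )
            )
        age = resolve_user_age(mentions, uid)

        cohort[uid] = CohortUser(
            user_id=uid,
            evidence=ev.channel,
            geo=geo if geo.state is not None else None,
            age=age,
        )

    return PipelineResult(
        cohort=cohort,
        evidences=evidences,
        decisions=decisions,
        n_input_records=len(records),
        n_retained_records=len(retained),
    )


def _latest_place(records: list[TweetRecord]):
    best = None
    best_key = None
    for rec in records:
        if rec.place is None or not rec.place.full_name:
            continue
        key = (rec.created_at, rec.tweet_id)
        if best_key is None or key > best_key:
            best, best_key = rec.place, key
    return best
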