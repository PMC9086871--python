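"""Reading, normalizing and writing tweet-stream records.

Two JSON dialects of tweet objects are supported:

* ``v1`` — the classic streaming payload with a nested ``user`` object,
  ``retweeted_status`` sub-records and an optional un-truncated
  ``extended_tweet.full_text`` / ``full_text`` field;
* ``v2`` — a flattened dialect where author fields live at the top level
  (``author_id``, ``author_name``, ``author_description``,
  ``author_location``) and the record carries ``referenced_tweets``.

``auto`` sniffs the dialect by key presence.  All timestamps are
normalized to UTC; records whose timestamp cannot be parsed receive a
minimal sentinel timestamp (and a warning) rather than being dropped,
so the cohort is never silently shrunk.
"""

from __future__ import annotations

import json
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Literal

from pydantic import BaseModel, Field, field_validator

__all__ = [
    "TweetRecord",
    "UserRecord",
    "Place",
    "ReadReport",
    "MalformedRecordError",
    "StreamFormatError",
    "normalize_record",
    "read_stream",
    "write_stream",
    "consolidate_users",
    "SENTINEL_TIMESTAMP",
]

#: Assigned to records whose created_at cannot be parsed.
SENTINEL_TIMESTAMP = datetime(1970, 1, 1, tzinfo=timezone.utc)

RETWEET_PREFIX = "RT @"


class MalformedRecordError(ValueError):
    """A raw record is missing a required key (tweet or author identifier)."""


class StreamFormatError(ValueError):
    """Raised when a majority of lines fail to parse — likely wrong dialect."""


class Place(BaseModel):
    """Structured place metadata attached to a tweet (rarely present)."""

    country_code: str = ""
    full_name: str = ""
    place_type: str = ""


class TweetRecord(BaseModel):
    """One normalized stream item."""

    tweet_id: str
    text: str = ""
    created_at: datetime = SENTINEL_TIMESTAMP
    user_id: str
    user_name: str = ""
    user_description: str = ""
    user_location: str = ""
    place: Place | None = None
    is_retweet: bool = False
    is_quote: bool = False

    @field_validator("tweet_id", "user_id")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v:
            raise ValueError("identifier must be non-empty")
        return v

    @field_validator("created_at")
    @classmethod
    def _utc(cls, v: datetime) -> datetime:
        if v.tzinfo is None:
            return v.replace(tzinfo=timezone.utc)
        return v.astimezone(timezone.utc)


class UserRecord(BaseModel):
    """Consolidated profile metadata for one user.

    Profile fields come from the user's most recent record; ``latest_seen``
    is the max ``created_at`` over that user's records.
    """

    user_id: str
    user_name: str = ""
    user_description: str = ""
    user_location: str = ""
    latest_seen: datetime = SENTINEL_TIMESTAMP


class ReadReport(BaseModel):
    """Line accounting for one read pass: parsed + skipped = total lines."""

    n_lines: int = 0
    n_records: int = 0
    n_skipped: int = 0
    skipped_lines: list[int] = Field(default_factory=list)


def _parse_timestamp(value: object) -> datetime:
    if isinstance(value, datetime):
        ts = value
    elif isinstance(value, (int, float)):
        ts = datetime.fromtimestamp(float(value) / 1000.0, tz=timezone.utc)
    elif isinstance(value, str) and value:
        ts = None
        for parser in (
            lambda s: datetime.strptime(s, "%a %b %d %H:%M:%S %z %Y"),
            lambda s: datetime.fromisoformat(s.replace("Z", "+00:00")),
        ):
            try:
                ts = parser(value)
                break
            except ValueError:
                continue
        if ts is None:
            warnings.warn(f"unparseable timestamp {value!r}; using sentinel")
            return SENTINEL_TIMESTAMP
    else:
        return SENTINEL_TIMESTAMP
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _sniff_dialect(raw: dict) -> str:
    if "tweet_id" in raw:
        return "normalized"  # our own write_stream output round-trips
    if "user" in raw and isinstance(raw["user"], dict):
        return "v1"
    if "author_id" in raw:
        return "v2"
    # v1 records always nest the author; default to v2 otherwise
    return "v2" if "referenced_tweets" in raw else "v1"


def _get_place(raw_place: object) -> Place | None:
    if not isinstance(raw_place, dict):
        return None
    return Place(
        country_code=str(raw_place.get("country_code") or ""),
        full_name=str(raw_place.get("full_name") or ""),
        place_type=str(raw_place.get("place_type") or ""),
    )


def normalize_record(
    raw: dict, dialect: Literal["v1", "v2", "auto"] = "auto"
) -> TweetRecord:
    """Normalize a parsed tweet JSON object into a :class:`TweetRecord`.

    Raises :class:`MalformedRecordError` when the tweet or author
    identifier is absent.
    """
    if dialect == "auto":
        dialect = _sniff_dialect(raw)

    if dialect == "normalized":
        return TweetRecord.model_validate(raw)

    tweet_id = raw.get("id_str") or raw.get("id")
    if tweet_id is None:
        raise MalformedRecordError("missing tweet identifier key 'id'/'id_str'")
    tweet_id = str(tweet_id)

    if dialect == "v1":
        user = raw.get("user") or {}
        user_id = user.get("id_str") or user.get("id")
        if user_id is None:
            raise MalformedRecordError("missing author identifier key 'user.id'")
        # prefer the full, un-truncated text
        extended = raw.get("extended_tweet") or {}
        text = (
            extended.get("full_text")
            or raw.get("full_text")
            or raw.get("text")
            or ""
        )
        is_retweet = "retweeted_status" in raw or text.startswith(RETWEET_PREFIX)
        is_quote = bool(raw.get("is_quote_status")) or "quoted_status" in raw
        return TweetRecord(
            tweet_id=tweet_id,
            text=text,
            created_at=_parse_timestamp(raw.get("created_at")),
            user_id=str(user_id),
            user_name=str(user.get("name") or user.get("screen_name") or ""),
            user_description=str(user.get("description") or ""),
            user_location=str(user.get("location") or ""),
            place=_get_place(raw.get("place")),
            is_retweet=is_retweet,
            is_quote=is_quote,
        )

    user_id = raw.get("author_id")
    if user_id is None:
        raise MalformedRecordError("missing author identifier key 'author_id'")
    text = raw.get("text") or ""
    refs = raw.get("referenced_tweets") or []
    ref_types = {r.get("type") for r in refs if isinstance(r, dict)}
    is_retweet = "retweeted" in ref_types or text.startswith(RETWEET_PREFIX)
    return TweetRecord(
        tweet_id=tweet_id,
        text=text,
        created_at=_parse_timestamp(raw.get("created_at")),
        user_id=str(user_id),
        user_name=str(raw.get("author_name") or raw.get("author_username") or ""),
        user_description=str(raw.get("author_description") or ""),
        user_location=str(raw.get("author_location") or ""),
        place=_get_place(raw.get("place")),
        is_retweet=is_retweet,
        is_quote="quoted" in ref_types,
    )


def read_stream(
    path: str | Path,
    dialect: Literal["v1", "v2", "auto"] = "auto",
    report: ReadReport | None = None,
) -> list[TweetRecord]:
    """Read a JSON Lines tweet stream, skipping (and counting) bad lines.

    Pass a :class:`ReadReport` to receive line accounting.  Raises
    :class:`StreamFormatError` when more than half of non-empty lines
    are malformed, which usually means the wrong dialect was forced.
    """
    path = Path(path)
    rep = report if report is not None else ReadReport()
    records: list[TweetRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rep.n_lines += 1
            try:
                raw = json.loads(line)
                if not isinstance(raw, dict):
                    raise MalformedRecordError("line is not a JSON object")
                records.append(normalize_record(raw, dialect))
            except (json.JSONDecodeError, MalformedRecordError, ValueError):
                rep.n_skipped += 1
                rep.skipped_lines.append(lineno)
                continue
    rep.n_records = len(records)
    if rep.n_lines > 0 and rep.n_skipped * 2 > rep.n_lines:
        raise StreamFormatError(
            f"{rep.n_skipped}/{rep.n_lines} lines malformed; "
            "check the --dialect setting"
        )
    return records


def write_stream(records: Iterable[TweetRecord], path: str | Path) -> int:
    """Write normalized records as JSON Lines; returns the count written."""
    n = 0
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.model_dump_json() + "\n")
            n += 1
    return n


def _record_sort_key(rec: TweetRecord) -> tuple:
    # recency first; ties broken by lexicographically larger tweet_id
    return (rec.created_at, rec.tweet_id)


def consolidate_users(records: Iterable[TweetRecord]) -> dict[str, UserRecord]:
    """One :class:`UserRecord` per distinct user_id.

    Profile fields are taken from the user's most recent record, ties
    broken by lexicographically larger tweet_id (deterministic and
    dialect-independent).
    """
    latest: dict[str, TweetRecord] = {}
    for rec in records:
        cur = latest.get(rec.user_id)
        if cur is None or _record_sort_key(rec) > _record_sort_key(cur):
            latest[rec.user_id] = rec
    return {
        uid: UserRecord(
            user_id=uid,
            user_name=rec.user_name,
            user_description=rec.user_description,
            user_location=rec.user_location,
            latest_seen=rec.created_at,
        )
        for uid, rec in latest.items()
    }


def _iter_user_groups(
    records: Iterable[TweetRecord],
) -> Iterator[tuple[str, list[TweetRecord]]]:
    groups: dict[str, list[TweetRecord]] = {}
    for rec in records:
        groups.setdefault(rec.user_id, []).append(rec)
    yield from groups.items()
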