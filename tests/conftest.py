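from datetime import datetime, timezone

import pytest

from msmcohort.geo import load_default_gazetteer
from msmcohort.patterns import compile_pattern_set
from msmcohort.records import TweetRecord


@pytest.fixture(scope="session")
def pattern_set():
    return compile_pattern_set()


@pytest.fixture(scope="session")
def gazetteer():
    return load_default_gazetteer()


def make_tweet(
    tweet_id="t1",
    text="hello",
    user_id="u1",
    created_at=None,
    **kwargs,
):
    return TweetRecord(
        tweet_id=tweet_id,
        text=text,
        user_id=user_id,
        created_at=created_at or datetime(2020, 9, 1, tzinfo=timezone.utc),
        **kwargs,
    )


@pytest.fixture
def tweet_factory():
    return make_tweet
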