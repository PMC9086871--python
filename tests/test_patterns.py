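"""Pattern grammar compilation and self-report matching."""

import pytest

from msmcohort.patterns import (
    Channel,
    PatternConfigError,
    classify_user,
    compile_pattern_set,
    match_profile,
    match_tweet_text,
)
from msmcohort.records import UserRecord

MINI_CFG = {
    "identity_terms": ["gay", "bi"],
    "person_terms": ["man", "guy"],
    "collective_terms": [],
    "tweet_templates": [
        {"id": "as_a", "pattern": "as\\s+an?\\s+{identity}\\s+{person}"}
    ],
    "profile_templates": [
        {"id": "pp", "pattern": "{identity}\\s+{person}"}
    ],
}


class TestCompile:
    def test_cross_product_expansion(self):
        ps = compile_pattern_set(MINI_CFG)
        assert len(ps.tweet_patterns) == 4  # 2 identity x 2 person x 1 template

    def test_unknown_placeholder_is_config_error(self):
        cfg = dict(MINI_CFG)
        cfg["tweet_templates"] = [{"id": "bad", "pattern": "an? {adjective} {person}"}]
        with pytest.raises(PatternConfigError, match="adjective"):
            compile_pattern_set(cfg)

    def test_empty_term_list_is_config_error(self):
        cfg = dict(MINI_CFG, identity_terms=[])
        with pytest.raises(PatternConfigError, match="identity"):
            compile_pattern_set(cfg)

    def test_default_config_compiles(self, pattern_set):
        assert pattern_set.n_surface_patterns > 0


# The five exemplar texts the matcher must fire on in default mode;
# the annotation layer, not the matcher, separates TP from FP.
EXEMPLAR_TWEETS = [
    (
        "End the FDA's discriminatory and unscientific policy against gay "
        "men like me donating blood.",
        "like_me",
    ),
    (
        "As a bi guy we get so little representation, and almost all of its "
        "negative. It's frustrating.",
        "as_a",
    ),
    (
        "Today, we remember Matthew Shepard who's life was cut short as a "
        "result of a hate crime due to his identity as a gay male.",
        "as_a",
    ),
]


class TestTweetMatching:
    @pytest.mark.parametrize("text,template", EXEMPLAR_TWEETS)
    def test_exemplar_tweets_match(self, pattern_set, text, template):
        m = match_tweet_text(text, pattern_set)
        assert m is not None and m.template_id == template
        assert text[m.matched_span[0] : m.matched_span[1]] == m.matched_text

    def test_identity_without_anchor_does_not_match(self, pattern_set):
        assert match_tweet_text("I love my gay friends", pattern_set) is None

    def test_bi_requires_word_boundary(self, pattern_set):
        assert match_tweet_text("I'm a big guy", pattern_set) is None
        assert match_tweet_text("as a bird man I fly", pattern_set) is None
        assert match_tweet_text("as a bi guy I am fine", pattern_set) is not None

    def test_case_insensitive(self, pattern_set):
        assert match_tweet_text("AS A GAY MAN I THRIVE", pattern_set) is not None

    def test_leftmost_match_wins(self, pattern_set):
        text = "being a gay man and, yes, as a gay man, I'll say it twice"
        m = match_tweet_text(text, pattern_set)
        assert m.matched_span[0] == 0 and m.template_id == "being_a"

    def test_determinism(self, pattern_set):
        text = EXEMPLAR_TWEETS[0][0]
        assert match_tweet_text(text, pattern_set) == match_tweet_text(
            text, pattern_set
        )

    def test_adding_template_never_removes_match(self, pattern_set):
        cfg = {
            "identity_terms": pattern_set.identity_terms,
            "person_terms": pattern_set.person_terms,
            "collective_terms": pattern_set.collective_terms,
            "tweet_templates": [
                {"id": "as_a", "pattern": "as\\s+an?\\s+(?:\\w+\\s+){0,2}{identity}\\s+{person}"},
            ],
            "profile_templates": [{"id": "pp", "pattern": "{identity}\\s+{person}"}],
        }
        small = compile_pattern_set(cfg)
        cfg_bigger = dict(cfg)
        cfg_bigger["tweet_templates"] = cfg["tweet_templates"] + [
            {"id": "like_me", "pattern": "{identity}\\s+{person_or_people}\\s+like\\s+me"}
        ]
        bigger = compile_pattern_set(cfg_bigger)
        for text, _ in EXEMPLAR_TWEETS:
            if match_tweet_text(text, small) is not None:
                assert match_tweet_text(text, bigger) is not None

    def test_strict_mode_suppresses_third_person(self, pattern_set):
        memorial = EXEMPLAR_TWEETS[2][0]
        assert match_tweet_text(memorial, pattern_set) is not None
        assert match_tweet_text(memorial, pattern_set, mode="strict") is None
        # first-person reports survive strict mode
        assert (
            match_tweet_text(EXEMPLAR_TWEETS[1][0], pattern_set, mode="strict")
            is not None
        )


class TestProfileMatching:
    def test_proud_profile_matches(self, pattern_set):
        u = UserRecord(user_id="a", user_description="A proud black gay guy.")
        m = match_profile(u, pattern_set)
        assert m is not None and m.channel is Channel.PROFILE

    def test_transnb_profile_matches_default_but_not_strict(self, pattern_set):
        u = UserRecord(
            user_id="b",
            user_description=(
                "50+ gay trans man, writer, film and food lover. "
                "He/him OR they/them."
            ),
        )
        assert match_profile(u, pattern_set) is not None
        assert match_profile(u, pattern_set, mode="strict") is None

    def test_empty_profile_no_match(self, pattern_set):
        u = UserRecord(user_id="c", user_description="", user_name="Taylor")
        assert match_profile(u, pattern_set) is None

    def test_display_name_scanned_after_description(self, pattern_set):
        u = UserRecord(user_id="d", user_description="runner", user_name="gay guy dave")
        m = match_profile(u, pattern_set)
        assert m is not None


class TestClassifyUser:
    def test_tweet_channel(self, pattern_set, tweet_factory):
        u = UserRecord(user_id="u1", user_description="runner")
        tweets = [tweet_factory(text="as a gay man I am tired", user_id="u1")]
        ev = classify_user(tweets, u, pattern_set)
        assert ev.channel is Channel.TWEET and ev.tweet_id == "t1"

    def test_both_channels(self, pattern_set, tweet_factory):
        u = UserRecord(user_id="u1", user_description="proud gay guy here")
        tweets = [tweet_factory(text="as a gay man I am tired", user_id="u1")]
        assert classify_user(tweets, u, pattern_set).channel is Channel.BOTH

    def test_quoted_only_match_yields_none(self, pattern_set, tweet_factory):
        u = UserRecord(user_id="u1", user_description="runner")
        tweets = [tweet_factory(text='"I am a gay man," he said.', user_id="u1")]
        assert classify_user(tweets, u, pattern_set) is None

    def test_mixed_user_ids_contract_error(self, pattern_set, tweet_factory):
        u = UserRecord(user_id="u1")
        with pytest.raises(ValueError, match="belongs"):
            classify_user([tweet_factory(user_id="u2")], u, pattern_set)

    def test_earliest_matching_tweet_is_provenance(self, pattern_set, tweet_factory):
        from datetime import datetime, timezone

        u = UserRecord(user_id="u1")
        early = tweet_factory(
            tweet_id="a",
            text="as a gay man I was here first",
            user_id="u1",
            created_at=datetime(2020, 9, 1, tzinfo=timezone.utc),
        )
        late = tweet_factory(
            tweet_id="b",
            text="being a gay man is great",
            user_id="u1",
            created_at=datetime(2020, 9, 5, tzinfo=timezone.utc),
        )
        ev = classify_user([late, early], u, pattern_set)
        assert ev.tweet_id == "a"
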