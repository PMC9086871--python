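"""Generator/pipeline co-tests on labeled synthetic corpora."""

import json

import pytest

from msmcohort.noise import FilterVerdict, detect_reported_speech, filter_stream
from msmcohort.patterns import compile_pattern_set, match_profile, match_tweet_text
from msmcohort.pipeline import run_pipeline
from msmcohort.records import UserRecord, consolidate_users, normalize_record
from msmcohort.synthetic import (
    CorpusSpec,
    expected_precision,
    generate_corpus,
    score_pipeline,
    write_corpus,
)


def normalized(spec):
    raw, truth = generate_corpus(spec)
    return [normalize_record(r) for r in raw], truth


class TestSpecValidation:
    def test_rates_must_be_fractions(self):
        with pytest.raises(ValueError, match="outside"):
            CorpusSpec(tp_tweet_rate=1.5)

    def test_overlap_cannot_exceed_channel_rate(self):
        with pytest.raises(ValueError, match="both"):
            CorpusSpec(tp_tweet_rate=0.1, tp_profile_rate=0.5, tp_both_rate=0.2)

    def test_role_mass_capped_at_one(self):
        with pytest.raises(ValueError, match="sum"):
            CorpusSpec(
                tp_tweet_rate=0.6, tp_profile_rate=0.5, tp_both_rate=0.0,
                fp_thirdperson_rate=0.0, fp_transnb_rate=0.0,
            )


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        spec = CorpusSpec(n_users=200, seed=11)
        paths = []
        for run in (1, 2):
            c = tmp_path / f"c{run}.jsonl"
            t = tmp_path / f"t{run}.csv"
            write_corpus(spec, c, t)
            paths.append((c.read_bytes(), t.read_bytes()))
        assert paths[0] == paths[1]

    def test_different_seed_differs(self, tmp_path):
        a, _ = generate_corpus(CorpusSpec(n_users=100, seed=1))
        b, _ = generate_corpus(CorpusSpec(n_users=100, seed=2))
        assert a != b


@pytest.fixture(scope="module")
def run():
    spec = CorpusSpec(n_users=800, seed=21)
    raw, truth = generate_corpus(spec)
    records = [normalize_record(r) for r in raw]
    return spec, raw, truth, records


class TestCoTestedInvariants:
    """The generator and the matcher/filter are two sides of one contract."""

    def test_generated_tps_always_match_default_patterns(self, run, pattern_set):
        _, raw, truth, records = run
        users = consolidate_users(records)
        retained, _ = filter_stream(records)
        by_user = {}
        for rec in retained:
            by_user.setdefault(rec.user_id, []).append(rec)
        for row in truth.itertuples():
            if not row.is_true_positive:
                continue
            u = users[row.user_id]
            if row.channel in ("profile", "both"):
                assert match_profile(u, pattern_set) is not None
            if row.channel in ("tweet", "both"):
                hit = any(
                    match_tweet_text(r.text, pattern_set) is not None
                    for r in by_user.get(row.user_id, [])
                )
                assert hit, f"TP tweet user {row.user_id} has no matching tweet"

    def test_generated_retweets_always_dropped(self, run):
        _, _, _, records = run
        rts = [r for r in records if r.text.startswith("RT @")]
        assert rts, "corpus should contain retweets at the default rate"
        _, decisions = filter_stream(records)
        verdicts = {d.tweet_id: d.verdict for d in decisions}
        assert all(verdicts[r.tweet_id] is FilterVerdict.DROP_RETWEET for r in rts)

    def test_cohort_is_exactly_the_should_match_set(self, run):
        # TPs and decoys all enter the cohort; negatives never do — the
        # precondition for the analytic mixture precision
        _, _, truth, records = run
        cohort = run_pipeline(records).cohort
        expected = set(truth.loc[truth["should_match"], "user_id"])
        assert set(cohort) == expected

    def test_reported_speech_items_always_flagged(self, run, pattern_set):
        _, _, _, records = run
        flagged = 0
        for rec in records:
            if rec.text.startswith("RT @"):
                continue
            m = match_tweet_text(rec.text, pattern_set)
            if m is None:
                continue
            reported, _ = detect_reported_speech(rec.text, m.matched_span)
            if '"' in rec.text or "he said" in rec.text or "he told" in rec.text:
                assert reported, rec.text
                flagged += 1
        assert flagged > 0


class TestPipelineOnSyntheticTruth:
    def test_decoy_free_corpus_perfect_precision_and_recall(self):
        spec = CorpusSpec(
            n_users=1000, seed=5,
            tp_tweet_rate=0.5, tp_profile_rate=0.3, tp_both_rate=0.1,
            fp_thirdperson_rate=0.0, fp_transnb_rate=0.0,
        )
        records, truth = normalized(spec)
        result = run_pipeline(records)
        scores = score_pipeline(result.cohort, truth)
        assert scores["precision"] == 1.0
        assert scores["recall"] == 1.0
        assert scores["state_accuracy"] == 1.0
        assert scores["county_accuracy"] == 1.0
        assert scores["age_accuracy"] == 1.0

    def test_all_decoy_corpus_zero_precision(self):
        spec = CorpusSpec(
            n_users=200, seed=6,
            tp_tweet_rate=0.0, tp_profile_rate=0.0, tp_both_rate=0.0,
            fp_thirdperson_rate=1.0, fp_transnb_rate=0.0,
        )
        records, truth = normalized(spec)
        result = run_pipeline(records)
        assert len(result.cohort) == 200
        assert score_pipeline(result.cohort, truth)["precision"] == 0.0

    def test_empty_cohort_has_absent_precision(self):
        spec = CorpusSpec(
            n_users=50, seed=7,
            tp_tweet_rate=0.0, tp_profile_rate=0.0, tp_both_rate=0.0,
            fp_thirdperson_rate=0.0, fp_transnb_rate=0.0,
            reported_speech_rate=0.0,
        )
        records, truth = normalized(spec)
        result = run_pipeline(records)
        assert result.cohort == {}
        scores = score_pipeline(result.cohort, truth)
        assert scores["precision"] is None and scores["recall"] is None

    def test_unknown_cohort_user_contract_error(self):
        from msmcohort.cohort import CohortUser
        from msmcohort.patterns import Channel

        spec = CorpusSpec(n_users=20, seed=8)
        _, truth = normalized(spec)
        ghost = {"zz": CohortUser("zz", Channel.TWEET)}
        with pytest.raises(ValueError, match="absent"):
            score_pipeline(ghost, truth)

    def test_strict_mode_trades_recall_for_precision(self):
        spec = CorpusSpec(n_users=1500, seed=9)
        records, truth = normalized(spec)
        default = score_pipeline(run_pipeline(records).cohort, truth)
        strict = score_pipeline(run_pipeline(records, mode="strict").cohort, truth)
        assert default["precision"] >= 0.80
        assert strict["precision"] > default["precision"]
        assert strict["recall"] <= default["recall"]

    def test_referential_integrity_and_nested_denominators(self, gazetteer):
        spec = CorpusSpec(n_users=600, seed=10)
        records, _ = normalized(spec)
        cohort = run_pipeline(records).cohort
        state_resolved = {u for u, c in cohort.items() if c.geo and c.geo.state}
        county_resolved = {u for u, c in cohort.items() if c.geo and c.geo.county}
        assert county_resolved <= state_resolved
        for uid in county_resolved:
            c = cohort[uid]
            assert gazetteer.has_county(c.geo.county, c.geo.state)


class TestAnalyticMixture:
    def test_expected_precision_formula(self):
        spec = CorpusSpec(
            tp_tweet_rate=0.4, tp_profile_rate=0.2, tp_both_rate=0.1,
            fp_thirdperson_rate=0.2, fp_transnb_rate=0.1,
        )
        # TP mass 0.5, matched mass 0.8
        assert expected_precision(spec) == pytest.approx(0.625)

    def test_measured_precision_converges_to_mixture_value(self):
        # law of large numbers at 10^4 users, 3 binomial SE tolerance
        spec = CorpusSpec(
            n_users=10_000, seed=13,
            tp_tweet_rate=0.425, tp_profile_rate=0.425, tp_both_rate=0.0,
            fp_thirdperson_rate=0.075, fp_transnb_rate=0.075,
        )
        p = expected_precision(spec)
        assert p == pytest.approx(0.85)
        records, truth = normalized(spec)
        scores = score_pipeline(run_pipeline(records).cohort, truth)
        n_matched = scores["n_cohort"]
        se = (p * (1 - p) / n_matched) ** 0.5
        assert abs(scores["precision"] - p) <= 3 * se
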