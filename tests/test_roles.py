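"""Sentiment banding, attitude aggregation, behavior taxonomy, stakeholders."""

import pytest

from echochamber import (
    SentimentBand,
    UserActivityCounts,
    activity_counts,
    classify_all,
    classify_behavior,
    load_default_lexicon,
    match_stakeholder,
    sentiment_label,
    user_attitude,
)
from echochamber.errors import ConfigurationError, UndefinedRoleError

from conftest import make_corpus

MEANS = {
    "tweets_posted": 10.0,
    "retweets_sent": 5.0,
    "retweets_received": 20.0,
    "comments_sent": 5.0,
    "comments_received": 5.0,
}


@pytest.mark.parametrize(
    "alpha,expected",
    [(0.95, "positive"), (0.6, "positive"), (0.5, "neutral"), (0.4, "negative"), (0.1, "negative")],
)
def test_sentiment_band(alpha, expected):
    assert sentiment_label(alpha) == expected


def test_sentiment_band_validation():
    with pytest.raises(ValueError):
        sentiment_label(1.2)
    with pytest.raises(ConfigurationError):
        SentimentBand(neg_max=0.7, pos_min=0.6)


def test_user_attitude_modal_and_ties():
    assert user_attitude(["positive", "positive", "negative"]) == "positive"
    assert user_attitude(["positive", "negative"]) == "neutral"
    assert user_attitude(["neutral"]) == "neutral"
    with pytest.raises(UndefinedRoleError):
        user_attitude([])


@pytest.mark.parametrize(
    "counts,flags,expected",
    [
        # high speaker: 1500/10 = 150 >= 100
        (dict(tweets_posted=10, retweets_received=1500), {}, "high_speaker"),
        (dict(tweets_posted=10, retweets_received=150), {}, "medium_speaker"),
        (dict(tweets_posted=10, retweets_received=35, retweets_sent=1), {}, "low_speaker"),
        # isolator: all four interaction counts zero, regardless of tweets
        (dict(tweets_posted=3), {}, "isolator"),
        (dict(tweets_posted=0), {}, "isolator"),
        # networker: tweets >= mean, rr >= mean, rr/rs >= 0.5
        (dict(tweets_posted=12, retweets_received=25, retweets_sent=20), {}, "networker"),
        # monologist: tweets >= mean, rr/tweets <= 0.3
        (dict(tweets_posted=12, retweets_received=3, retweets_sent=1), {}, "monologist"),
        # retweeter beats replicator when both fire (precedence);
        # rr/tweets = 0.5 blocks monologist, rr < mean blocks networker
        (dict(tweets_posted=10, retweets_received=5, retweets_sent=6, comments_sent=7),
         {}, "retweeter"),
        # replicator can fire with few originals
        (dict(tweets_posted=2, comments_sent=9, retweets_received=1), {}, "replicator"),
        (dict(tweets_posted=1, retweets_sent=1), {}, "common"),
        # automatic needs both flags
        (dict(tweets_posted=1, comments_sent=5),
         dict(duplicate_comment_flag=True, profile_blank_flag=True), "automatic"),
        (dict(tweets_posted=1, comments_sent=5),
         dict(duplicate_comment_flag=True, profile_blank_flag=False), "replicator"),
        # ratio rules never divide by zero: 0 originals, retweets received
        (dict(tweets_posted=0, retweets_received=7, retweets_sent=30), {}, "common"),
    ],
)
def test_classify_behavior(counts, flags, expected):
    c = UserActivityCounts(**counts)
    assert classify_behavior(c, MEANS, **flags) == expected


def test_doubling_counts_and_means_preserves_ratio_rules():
    c = UserActivityCounts(tweets_posted=10, retweets_received=35, retweets_sent=1)
    doubled = UserActivityCounts(
        tweets_posted=20, retweets_received=70, retweets_sent=2
    )
    means2 = {k: 2 * v for k, v in MEANS.items()}
    assert classify_behavior(c, MEANS) == classify_behavior(doubled, means2)


def test_activity_counts_from_corpus():
    corpus = make_corpus(
        users=[{"user_id": u} for u in ("ua", "ub")],
        tweets=[
            {"tweet_id": "o1", "author_id": "ua"},
            {"tweet_id": "r1", "author_id": "ub", "kind": "retweet",
             "parent_id": "o1", "root_original_id": "o1"},
            {"tweet_id": "c1", "author_id": "ub", "kind": "comment",
             "parent_id": "o1", "root_original_id": "o1"},
        ],
    )
    counts = activity_counts(corpus)
    assert counts.loc["ua"].tolist() == [1, 0, 1, 0, 1]  # posted, rs, rr, cs, cr
    assert counts.loc["ub"].tolist() == [0, 1, 0, 1, 0]


def test_partition_every_user_gets_one_category(small_synthetic):
    corpus, _ = small_synthetic
    table = classify_all(corpus)
    assert len(table) == len(corpus.users)
    assert table["behavior"].notna().all()


def test_isolator_archetype_recovered(small_synthetic):
    corpus, users = small_synthetic
    table = classify_all(corpus)
    iso = users.loc[users["archetype"] == "isolator", "user_id"]
    frac = (table.loc[iso, "behavior"] == "isolator").mean()
    assert frac >= 0.9


@pytest.mark.parametrize(
    "text,expected",
    [
        ("works at the city hospital", "hospital"),
        ("", "common_personnel"),
        ("nothing matching here", "common_personnel"),
        # earlier lexicon row wins on multiple hits
        ("government hospital unit", "government"),
        ("Provincial Daily NEWSPAPER editor", "traditional_media"),  # case-insensitive
    ],
)
def test_match_stakeholder(text, expected):
    lex = load_default_lexicon()
    assert match_stakeholder(text, lex) == expected


def test_lexicon_has_eleven_ordered_types():
    lex = load_default_lexicon()
    assert len(lex.entries) == 11
    assert lex.fallback == "common_personnel"
    assert all(kws for t, kws in lex.entries[:-1])
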