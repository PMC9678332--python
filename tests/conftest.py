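import numpy as np
import pandas as pd
import pytest

from echochamber import Corpus, GeneratorConfig, generate


def make_corpus(users: list[dict], tweets: list[dict]) -> Corpus:
    """Build a corpus from row dicts, filling optional fields."""
    udf = pd.DataFrame(
        [
            {
                "user_id": u["user_id"],
                "stakeholder_type": u.get("stakeholder_type", "common_personnel"),
                "profile_text": u.get("profile_text", "ordinary netizen"),
            }
            for u in users
        ]
    ).astype("string")
    rows = []
    for t in tweets:
        rows.append(
            {
                "tweet_id": t["tweet_id"],
                "author_id": t["author_id"],
                "kind": t.get("kind", "original"),
                "parent_id": t.get("parent_id"),
                "root_original_id": t.get("root_original_id", t["tweet_id"]),
                "topic": t.get("topic", "conspiracy"),
                "alpha": t.get("alpha", 0.8),
            }
        )
    tdf = pd.DataFrame(rows)
    for col in ("tweet_id", "author_id", "kind", "parent_id", "root_original_id", "topic"):
        tdf[col] = tdf[col].astype("string")
    tdf["alpha"] = tdf["alpha"].astype(float)
    return Corpus(users=udf, tweets=tdf)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_users=400, seed=11, h_attitude=0.6, h_topic=0.5)


@pytest.fixture(scope="session")
def small_synthetic(small_config):
    """A 400-user synthetic corpus shared across tests (read-only)."""
    corpus, users = generate(small_config)
    return corpus, users


@pytest.fixture()
def two_original_corpus():
    """Two originals by distinct authors plus one user retweeting both."""
    return make_corpus(
        users=[{"user_id": u} for u in ("ua", "ub", "uc")],
        tweets=[
            {"tweet_id": "o1", "author_id": "ua", "topic": "conspiracy"},
            {"tweet_id": "o2", "author_id": "ub", "topic": "severity"},
            {
                "tweet_id": "r1",
                "author_id": "uc",
                "kind": "retweet",
                "parent_id": "o1",
                "root_original_id": "o1",
                "topic": "conspiracy",
            },
            {
                "tweet_id": "r2",
                "author_id": "uc",
                "kind": "retweet",
                "parent_id": "o2",
                "root_original_id": "o2",
                "topic": "severity",
            },
        ],
    )
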