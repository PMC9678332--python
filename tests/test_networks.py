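"""Construction rules for the information and user network families."""

import pytest

from echochamber import build_info_network, build_user_network
from echochamber.errors import EmptyCorpusError

from conftest import make_corpus


def test_common_user_creates_unit_weight_info_edge(two_original_corpus):
    g = build_info_network(two_original_corpus, "global")
    assert set(g.nodes) == {"o1", "o2"}
    assert g["o1"]["o2"]["weight"] == 1
    assert g.nodes["o1"]["topic"] == "conspiracy"
    assert not g.is_directed()


def test_info_weight_counts_distinct_users_not_events():
    corpus = make_corpus(
        users=[{"user_id": u} for u in ("ua", "ub", "uc")],
        tweets=[
            {"tweet_id": "o1", "author_id": "ua"},
            {"tweet_id": "o2", "author_id": "ub"},
            # uc retweets o1 twice and o2 once: still one common user
            {"tweet_id": "r1", "author_id": "uc", "kind": "retweet",
             "parent_id": "o1", "root_original_id": "o1"},
            {"tweet_id": "r2", "author_id": "uc", "kind": "retweet",
             "parent_id": "o1", "root_original_id": "o1"},
            {"tweet_id": "r3", "author_id": "uc", "kind": "retweet",
             "parent_id": "o2", "root_original_id": "o2"},
        ],
    )
    g = build_info_network(corpus, "retweet")
    assert g["o1"]["o2"]["weight"] == 1


def test_info_retweet_mode_ignores_comments(two_original_corpus):
    corpus = two_original_corpus
    corpus.tweets.loc[corpus.tweets["kind"] == "retweet", "kind"] = "comment"
    g = build_info_network(corpus, "retweet")
    assert set(g.nodes) == {"o1", "o2"} and g.number_of_edges() == 0


def test_user_edge_weight_counts_interactions():
    corpus = make_corpus(
        users=[{"user_id": "ui"}, {"user_id": "uj"}],
        tweets=[
            {"tweet_id": "o1", "author_id": "uj"},
            {"tweet_id": "c1", "author_id": "ui", "kind": "comment",
             "parent_id": "o1", "root_original_id": "o1"},
            {"tweet_id": "c2", "author_id": "ui", "kind": "comment",
             "parent_id": "o1", "root_original_id": "o1"},
        ],
    )
    g = build_user_network(corpus, "comment")
    assert g["ui"]["uj"]["weight"] == 2
    assert g.is_directed()


def test_retweet_of_retweet_credits_immediate_parent_author():
    corpus = make_corpus(
        users=[{"user_id": u} for u in ("ui", "uj", "uk")],
        tweets=[
            {"tweet_id": "o1", "author_id": "uk"},
            {"tweet_id": "r1", "author_id": "uj", "kind": "retweet",
             "parent_id": "o1", "root_original_id": "o1"},
            {"tweet_id": "r2", "author_id": "ui", "kind": "retweet",
             "parent_id": "r1", "root_original_id": "o1"},
        ],
    )
    g = build_user_network(corpus, "retweet")
    assert g.has_edge("ui", "uj") and not g.has_edge("ui", "uk")
    assert g.has_edge("uj", "uk")


def test_self_interaction_excluded():
    corpus = make_corpus(
        users=[{"user_id": "ui"}],
        tweets=[
            {"tweet_id": "o1", "author_id": "ui"},
            {"tweet_id": "r1", "author_id": "ui", "kind": "retweet",
             "parent_id": "o1", "root_original_id": "o1"},
        ],
    )
    g = build_user_network(corpus, "retweet")
    assert g.number_of_edges() == 0
    assert "ui" in g.nodes  # isolated author kept


def test_isolated_authors_switchable():
    corpus = make_corpus(
        users=[{"user_id": "ui"}, {"user_id": "uj"}],
        tweets=[
            {"tweet_id": "o1", "author_id": "ui"},
            {"tweet_id": "o2", "author_id": "uj"},
        ],
    )
    assert set(build_user_network(corpus, "global").nodes) == {"ui", "uj"}
    g = build_user_network(corpus, "global", include_isolated_authors=False)
    assert g.number_of_nodes() == 0


def test_user_global_weights_partition_by_relation(small_synthetic):
    """Interaction events split exactly between the retweet and comment layers."""
    corpus, _ = small_synthetic
    totals = {
        mode: sum(
            d["weight"] for _, _, d in build_user_network(corpus, mode).edges(data=True)
        )
        for mode in ("retweet", "comment", "global")
    }
    assert totals["global"] == totals["retweet"] + totals["comment"]


def test_info_global_weight_dominates_each_mode(small_synthetic):
    """Distinct common users over either relation can only grow; they do not
    partition (one user may reach original i by retweet and j by comment)."""
    corpus, _ = small_synthetic
    g_global = build_info_network(corpus, "global")
    for mode in ("retweet", "comment"):
        g = build_info_network(corpus, mode)
        for i, j, d in g.edges(data=True):
            assert g_global[i][j]["weight"] >= d["weight"]


def test_info_weight_bounded_by_distinct_interactors(small_synthetic):
    corpus, _ = small_synthetic
    g = build_info_network(corpus, "global")
    inter = corpus.interactions
    per_root = inter.groupby("root_original_id")["author_id"].nunique()
    for i, j, d in g.edges(data=True):
        assert d["weight"] <= min(per_root[i], per_root[j])


def test_user_network_node_count_bounded(small_synthetic):
    corpus, _ = small_synthetic
    g = build_user_network(corpus, "global")
    assert g.number_of_nodes() <= len(corpus.users)


def test_empty_corpus_rejected():
    import pandas as pd
    from echochamber import Corpus
    from echochamber.corpus import TWEET_COLUMNS, USER_COLUMNS

    empty = Corpus(
        users=pd.DataFrame([["ua", "common_personnel", ""]], columns=list(USER_COLUMNS)),
        tweets=pd.DataFrame(columns=list(TWEET_COLUMNS)),
    )
    with pytest.raises(EmptyCorpusError):
        build_info_network(empty, "global")
    with pytest.raises(EmptyCorpusError):
        build_user_network(empty, "global")
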