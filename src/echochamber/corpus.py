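"""Corpus container, CSV interchange, structural validation, graph export.

A corpus is a pair of tables:

``users``
    one row per account — ``user_id``, ``stakeholder_type``, ``profile_text``.
``tweets``
    one row per post — ``tweet_id``, ``author_id``, ``kind`` (original /
    retweet / comment), ``parent_id`` (empty for originals), ``root_original_id``
    (the original at the end of the parent chain), ``topic`` (one of the 13
    Health Belief Model topics, set on originals and inherited by reposts),
    and ``alpha``, the sentiment positive-probability in [0, 1].

Validation is structural only: referential integrity, vocabulary membership,
topic inheritance and the alpha range.  No text-content filtering is applied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import EmptyCorpusError, ReferentialIntegrityError, SchemaError
from .taxonomy import TOPICS, TWEET_KINDS

USER_COLUMNS = ("user_id", "stakeholder_type", "profile_text")
TWEET_COLUMNS = (
    "tweet_id",
    "author_id",
    "kind",
    "parent_id",
    "root_original_id",
    "topic",
    "alpha",
)

GRAPH_FORMATS = ("graphml", "gexf", "weighted-edge-list")


@dataclass
class Violation:
    """One validation failure: the offending record and the rule it broke."""

    record_id: str
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.record_id}: {self.detail}"


@dataclass
class Corpus:
    """Users + tweets tables; the single source every network derives from."""

    users: pd.DataFrame
    tweets: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in USER_COLUMNS if c not in self.users.columns]
        if missing:
            raise SchemaError(f"users table missing column(s): {missing}")
        missing = [c for c in TWEET_COLUMNS if c not in self.tweets.columns]
        if missing:
            raise SchemaError(f"tweets table missing column(s): {missing}")

    @property
    def originals(self) -> pd.DataFrame:
        return self.tweets[self.tweets["kind"] == "original"]

    @property
    def interactions(self) -> pd.DataFrame:
        return self.tweets[self.tweets["kind"] != "original"]

    def equals(self, other: "Corpus") -> bool:
        return self.users.reset_index(drop=True).equals(
            other.users.reset_index(drop=True)
        ) and self.tweets.reset_index(drop=True).equals(
            other.tweets.reset_index(drop=True)
        )


def _normalize_tweets(tweets: pd.DataFrame) -> pd.DataFrame:
    tweets = tweets.copy()
    for col in ("tweet_id", "author_id", "kind", "topic"):
        tweets[col] = tweets[col].astype("string")
    for col in ("parent_id", "root_original_id"):
        tweets[col] = tweets[col].astype("string").replace("", pd.NA)
    def _float(x):  # pd.to_numeric parses lossily; float() roundtrips exactly
        try:
            return float(x)
        except (TypeError, ValueError):
            return float("nan")

    tweets["alpha"] = tweets["alpha"].map(_float).astype(float)
    return tweets


def _normalize_users(users: pd.DataFrame) -> pd.DataFrame:
    users = users.copy()
    for col in USER_COLUMNS:
        users[col] = users[col].astype("string").fillna("")
    return users


def read_corpus(users_path: str | Path, tweets_path: str | Path) -> Corpus:
    """Read and validate a corpus from the two-CSV interchange format.

    Raises :class:`SchemaError` on missing columns or out-of-vocabulary
    ``kind`` values, and :class:`ReferentialIntegrityError` (carrying the
    offending tweet ids) on dangling ``parent_id`` references.  Row order is
    preserved.
    """
    users = pd.read_csv(users_path, dtype=str, keep_default_na=False)
    tweets = pd.read_csv(tweets_path, dtype=str, keep_default_na=False)

    missing = [c for c in USER_COLUMNS if c not in users.columns]
    if missing:
        raise SchemaError(f"users file missing column(s): {missing}")
    missing = [c for c in TWEET_COLUMNS if c not in tweets.columns]
    if missing:
        raise SchemaError(f"tweets file missing column(s): {missing}")

    bad_kind = sorted(set(tweets["kind"]) - set(TWEET_KINDS))
    if bad_kind:
        raise SchemaError(
            f"tweets 'kind' contains out-of-vocabulary value(s): {bad_kind}; "
            f"allowed: {list(TWEET_KINDS)}"
        )

    corpus = Corpus(users=_normalize_users(users), tweets=_normalize_tweets(tweets))

    known = set(corpus.tweets["tweet_id"])
    inter = corpus.interactions
    dangling = inter.loc[
        inter["parent_id"].isna() | ~inter["parent_id"].isin(known), "tweet_id"
    ]
    if len(dangling):
        raise ReferentialIntegrityError(
            f"{len(dangling)} retweet/comment row(s) reference a missing parent",
            offending_ids=list(dangling),
        )
    return corpus


def write_corpus(corpus: Corpus, users_path: str | Path, tweets_path: str | Path) -> None:
    """Write the two CSV files (UTF-8, RFC-4180 quoting; empty string = null)."""
    users = corpus.users[list(USER_COLUMNS)]
    tweets = corpus.tweets[list(TWEET_COLUMNS)].copy()
    for col in ("parent_id", "root_original_id"):
        tweets[col] = tweets[col].fillna("")
    users.to_csv(users_path, index=False, quoting=csv.QUOTE_MINIMAL)
    # %.17g keeps the alpha roundtrip bit-exact
    tweets.to_csv(tweets_path, index=False, quoting=csv.QUOTE_MINIMAL, float_format="%.17g")


def validate_corpus(corpus: Corpus) -> list[Violation]:
    """Check every structural invariant; return violations as data, not exceptions.

    Rules checked (rule name in parentheses): unique user and tweet ids
    (``unique_user_id``, ``unique_tweet_id``); kind vocabulary
    (``kind_vocabulary``); originals have no parent and a known topic
    (``original_no_parent``, ``topic_vocabulary``); interactions reference an
    existing parent (``dangling_parent``) and resolve to an original root
    (``root_resolution``); reposts inherit the root's topic
    (``topic_inheritance``); alpha in [0, 1] (``alpha_range``); authors exist
    in the users table (``unknown_author``).
    """
    out: list[Violation] = []
    users, tweets = corpus.users, corpus.tweets

    dup = users.loc[users["user_id"].duplicated(), "user_id"]
    out += [Violation(u, "unique_user_id", "duplicated user_id") for u in dup]
    dup = tweets.loc[tweets["tweet_id"].duplicated(), "tweet_id"]
    out += [Violation(t, "unique_tweet_id", "duplicated tweet_id") for t in dup]

    bad = tweets.loc[~tweets["kind"].isin(TWEET_KINDS)]
    out += [
        Violation(r.tweet_id, "kind_vocabulary", f"kind={r.kind!r}")
        for r in bad.itertuples()
    ]

    known_users = set(users["user_id"])
    bad = tweets.loc[~tweets["author_id"].isin(known_users)]
    out += [
        Violation(r.tweet_id, "unknown_author", f"author_id={r.author_id!r}")
        for r in bad.itertuples()
    ]

    originals = corpus.originals
    bad = originals.loc[originals["parent_id"].notna()]
    out += [
        Violation(r.tweet_id, "original_no_parent", f"parent_id={r.parent_id!r}")
        for r in bad.itertuples()
    ]
    bad = originals.loc[~originals["topic"].isin(TOPICS)]
    out += [
        Violation(r.tweet_id, "topic_vocabulary", f"topic={r.topic!r}")
        for r in bad.itertuples()
    ]

    kind_of = dict(zip(tweets["tweet_id"], tweets["kind"]))
    parent_of = dict(zip(tweets["tweet_id"], tweets["parent_id"]))
    topic_of = dict(zip(tweets["tweet_id"], tweets["topic"]))

    for r in corpus.interactions.itertuples():
        pid = r.parent_id
        if pd.isna(pid) or pid not in kind_of:
            out.append(Violation(r.tweet_id, "dangling_parent", f"parent_id={pid!r}"))
            continue
        # walk the parent chain to the original (cycle-safe)
        seen = set()
        cur = r.tweet_id
        while cur in parent_of and pd.notna(parent_of[cur]) and cur not in seen:
            seen.add(cur)
            cur = parent_of[cur]
        if kind_of.get(cur) != "original" or cur != r.root_original_id:
            out.append(
                Violation(
                    r.tweet_id,
                    "root_resolution",
                    f"root_original_id={r.root_original_id!r}, chain ends at {cur!r}",
                )
            )
        elif topic_of.get(cur) != r.topic:
            out.append(
                Violation(
                    r.tweet_id,
                    "topic_inheritance",
                    f"topic={r.topic!r} but root topic={topic_of.get(cur)!r}",
                )
            )

    bad = tweets.loc[
        tweets["alpha"].isna() | (tweets["alpha"] < 0) | (tweets["alpha"] > 1)
    ]
    out += [
        Violation(r.tweet_id, "alpha_range", f"alpha={r.alpha!r}")
        for r in bad.itertuples()
    ]
    return out


def export_graph(graph: nx.Graph, fmt: str, path: str | Path) -> None:
    """Write a constructed interaction graph as GraphML, GEXF or an edge list.

    Node attributes (topic / attitude) and edge weights are preserved by the
    XML formats; the weighted edge list keeps only topology and weights.
    """
    if graph.number_of_nodes() == 0:
        raise EmptyCorpusError("refusing to export an empty graph")
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "gexf":
        nx.write_gexf(graph, path)
    elif fmt == "weighted-edge-list":
        nx.write_weighted_edgelist(graph, path)
    else:
        raise ValueError(
            f"unsupported graph format {fmt!r}; choose one of {list(GRAPH_FORMATS)}"
        )


def import_graph(fmt: str, path: str | Path, directed: bool = False) -> nx.Graph:
    """Inverse of :func:`export_graph` (up to node/edge order)."""
    if fmt == "graphml":
        g = nx.read_graphml(path)
    elif fmt == "gexf":
        g = nx.read_gexf(path)
        # drop gexf viz/label bookkeeping so roundtrips compare clean
        for _, d in g.nodes(data=True):
            d.pop("label", None)
    elif fmt == "weighted-edge-list":
        create = nx.DiGraph if directed else nx.Graph
        g = nx.read_weighted_edgelist(path, create_using=create)
    else:
        raise ValueError(
            f"unsupported graph format {fmt!r}; choose one of {list(GRAPH_FORMATS)}"
        )
    return g
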