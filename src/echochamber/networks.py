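"""Construction of the two interaction-network families.

Information representational network (undirected, weighted)
    Nodes are original tweets, labeled by topic.  Two originals are linked if
    at least one user interacted (retweeted / commented, depending on mode)
    with both; the edge weight is the number of *distinct* common users.

User communication flow network (directed, weighted)
    Nodes are users, labeled by attitude.  An edge i -> j with weight w means
    user i retweeted or commented w times on tweets authored by j — crediting
    the author of the *immediate* parent tweet, so a retweet of a retweet
    links to the intermediate re-poster, not the root author.  Self-loops are
    dropped.

Both come in three modes: ``retweet``, ``comment`` and ``global`` (union).
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import networkx as nx
import pandas as pd

from .corpus import Corpus
from .errors import EmptyCorpusError, ReferentialIntegrityError
from .roles import SentimentBand, user_attitudes
from .taxonomy import MODES


def _mode_kinds(mode: str) -> set[str]:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {list(MODES)}, got {mode!r}")
    return {"retweet", "comment"} if mode == "global" else {mode}


def build_info_network(corpus: Corpus, mode: str = "global") -> nx.Graph:
    """Information representational network for the given interaction mode.

    Every original tweet is a node (topic as node attribute) even when it was
    never interacted with; edges carry the distinct-common-user count.
    """
    originals = corpus.originals
    if corpus.tweets.empty:
        raise EmptyCorpusError("corpus has no tweets")
    kinds = _mode_kinds(mode)

    g = nx.Graph(mode=mode, layer="information")
    for row in originals.itertuples():
        g.add_node(row.tweet_id, topic=row.topic)

    inter = corpus.tweets[corpus.tweets["kind"].isin(kinds)]
    touched = (
        inter.groupby("author_id")["root_original_id"]
        .agg(lambda s: sorted(set(s.dropna())))
    )
    for roots in touched:
        for i, j in combinations(roots, 2):
            if g.has_edge(i, j):
                g[i][j]["weight"] += 1
            else:
                g.add_edge(i, j, weight=1)
    return g


def build_user_network(
    corpus: Corpus,
    mode: str = "global",
    include_isolated_authors: bool = True,
    attitudes: Mapping[str, str] | pd.Series | None = None,
    band: SentimentBand = SentimentBand(),
) -> nx.DiGraph:
    """User communication flow network for the given interaction mode.

    Node attribute ``attitude`` comes from the modal-sentiment aggregation
    (or from ``attitudes`` if supplied, e.g. latent ground truth).  Authors
    with no interaction in the mode remain as isolated nodes unless
    ``include_isolated_authors`` is false.
    """
    if corpus.tweets.empty:
        raise EmptyCorpusError("corpus has no tweets")
    kinds = _mode_kinds(mode)

    parent_author = corpus.tweets.set_index("tweet_id")["author_id"]
    inter = corpus.tweets[corpus.tweets["kind"].isin(kinds)].copy()
    targets = inter["parent_id"].map(parent_author)
    if targets.isna().any():
        bad = inter.loc[targets.isna(), "tweet_id"].tolist()
        raise ReferentialIntegrityError(
            "interaction(s) whose parent author is missing", offending_ids=bad
        )
    inter["target_id"] = targets

    if attitudes is None:
        attitudes = user_attitudes(corpus, band)

    g = nx.DiGraph(mode=mode, layer="user")
    authors = pd.unique(corpus.tweets["author_id"])
    if include_isolated_authors:
        for u in authors:
            g.add_node(u)
    counts = (
        inter.loc[inter["author_id"] != inter["target_id"]]
        .groupby(["author_id", "target_id"])
        .size()
    )
    for (src, dst), w in counts.items():
        g.add_edge(src, dst, weight=int(w))
    nx.set_node_attributes(
        g, {u: attitudes.get(u, "neutral") for u in g.nodes}, "attitude"
    )
    return g
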