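"""User classification: sentiment/attitude, behavior taxonomy, stakeholder type.

Attitude
    Each tweet carries a sentiment positive-probability ``alpha``; a symmetric
    band maps it to negative (alpha <= neg_max), positive (alpha >= pos_min)
    or neutral.  A user's attitude is their modal tweet label, with ties
    resolved to neutral (a tied user expresses no dominant stance).

Behavior taxonomy
    Ten categories assigned by the first matching rule in a fixed precedence:
    automatic, isolator, high/medium/low speaker, networker, monologist,
    retweeter, replicator, common.  Speaker tiers compare retweets received
    with originals posted (ratio >= 100 / 10 / 3); the remaining rules compare
    a user's counts with population means over all users (zeros included).

Stakeholder type
    First keyword-list hit, in lexicon order, by case-insensitive substring
    matching on the profile text; ``common_personnel`` is the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError, UndefinedRoleError

# --------------------------------------------------------------------------
# sentiment

@dataclass(frozen=True)
class SentimentBand:
    """Thresholds splitting alpha into negative / neutral / positive."""

    neg_max: float = 0.4
    pos_min: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.neg_max < self.pos_min <= 1.0:
            raise ConfigurationError(
                f"require 0 <= neg_max < pos_min <= 1, got ({self.neg_max}, {self.pos_min})"
            )


def sentiment_label(alpha: float, band: SentimentBand = SentimentBand()) -> str:
    """Map a positive-probability alpha in [0, 1] to a sentiment label."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if alpha <= band.neg_max:
        return "negative"
    if alpha >= band.pos_min:
        return "positive"
    return "neutral"


def user_attitude(labels: Iterable[str]) -> str:
    """Modal sentiment label of a user's tweets; ties resolve to neutral."""
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    if not counts:
        raise UndefinedRoleError("attitude undefined: user has no labeled tweets")
    top = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == top]
    return winners[0] if len(winners) == 1 else "neutral"


def user_attitudes(corpus, band: SentimentBand = SentimentBand()) -> pd.Series:
    """Attitude per user over all their tweets; users with no tweets are absent."""
    tweets = corpus.tweets
    labels = tweets["alpha"].map(lambda a: sentiment_label(float(a), band))
    return (
        pd.DataFrame({"author_id": tweets["author_id"], "label": labels})
        .groupby("author_id", sort=True)["label"]
        .agg(lambda s: user_attitude(s.tolist()))
    )


# --------------------------------------------------------------------------
# behavior taxonomy

SPEAKER_TIERS = (("high_speaker", 100.0), ("medium_speaker", 10.0), ("low_speaker", 3.0))


@dataclass(frozen=True)
class UserActivityCounts:
    tweets_posted: int = 0
    retweets_sent: int = 0
    retweets_received: int = 0
    comments_sent: int = 0
    comments_received: int = 0


def _ratio_ge(num: float, den: float, thr: float) -> bool:
    """num/den >= thr, evaluating False (never raising) when den == 0."""
    return den > 0 and num / den >= thr


def _ratio_le(num: float, den: float, thr: float) -> bool:
    return den > 0 and num / den <= thr


def classify_behavior(
    counts: UserActivityCounts,
    means: Mapping[str, float],
    duplicate_comment_flag: bool = False,
    profile_blank_flag: bool = False,
) -> str:
    """Assign the single behavior category by first-match precedence.

    ``means`` holds population means of the five count fields computed over
    all users, zeros included.  Ratio rules with a zero denominator evaluate
    false rather than raising.
    """
    c = counts
    if duplicate_comment_flag and profile_blank_flag:
        return "automatic"
    if (
        c.retweets_sent == 0
        and c.retweets_received == 0
        and c.comments_sent == 0
        and c.comments_received == 0
    ):
        return "isolator"
    for name, thr in SPEAKER_TIERS:
        if _ratio_ge(c.retweets_received, c.tweets_posted, thr):
            return name
    if (
        c.tweets_posted >= means["tweets_posted"]
        and c.retweets_received >= means["retweets_received"]
        and _ratio_ge(c.retweets_received, c.retweets_sent, 0.5)
    ):
        return "networker"
    if c.tweets_posted >= means["tweets_posted"] and _ratio_le(
        c.retweets_received, c.tweets_posted, 0.3
    ):
        return "monologist"
    if c.tweets_posted >= means["tweets_posted"] and _ratio_ge(
        c.retweets_sent, c.tweets_posted, 0.5
    ):
        return "retweeter"
    if _ratio_ge(c.comments_sent, c.tweets_posted, 0.6):
        return "replicator"
    return "common"


def activity_counts(corpus) -> pd.DataFrame:
    """Per-user activity counts over the corpus, indexed by user_id.

    ``tweets_posted`` counts originals only; received counts are interaction
    events whose parent tweet the user authored.
    """
    tweets = corpus.tweets
    users = corpus.users["user_id"]
    out = pd.DataFrame(
        0,
        index=pd.Index(users, name="user_id"),
        columns=[
            "tweets_posted",
            "retweets_sent",
            "retweets_received",
            "comments_sent",
            "comments_received",
        ],
        dtype=int,
    )
    by_kind_author = tweets.groupby(["kind", "author_id"]).size()
    for kind, col in (
        ("original", "tweets_posted"),
        ("retweet", "retweets_sent"),
        ("comment", "comments_sent"),
    ):
        if kind in by_kind_author.index.get_level_values(0):
            s = by_kind_author[kind]
            out.loc[s.index.intersection(out.index), col] = s
    parent_author = tweets.set_index("tweet_id")["author_id"]
    inter = corpus.interactions
    recv = (
        inter.assign(target=inter["parent_id"].map(parent_author))
        .groupby(["kind", "target"])
        .size()
    )
    for kind, col in (("retweet", "retweets_received"), ("comment", "comments_received")):
        if kind in recv.index.get_level_values(0):
            s = recv[kind]
            out.loc[s.index.intersection(out.index), col] = s
    return out


def classify_all(corpus) -> pd.DataFrame:
    """Behavior category for every user in the corpus, with the counts used.

    The duplicate-comment flag is raised when a user posts more than one
    comment under the same parent tweet; the blank-profile flag when the
    profile text is empty.  Both must hold for the automatic class.
    """
    counts = activity_counts(corpus)
    means = counts.mean().to_dict()
    inter = corpus.tweets[corpus.tweets["kind"] == "comment"]
    dup_users = set(
        inter.groupby(["author_id", "parent_id"])
        .size()
        .loc[lambda s: s > 1]
        .index.get_level_values(0)
    )
    blank = dict(
        zip(corpus.users["user_id"], corpus.users["profile_text"].fillna("") == "")
    )
    cats = []
    for row in counts.itertuples():
        fields = {k: v for k, v in row._asdict().items() if k != "Index"}
        cats.append(
            classify_behavior(
                UserActivityCounts(**fields),
                means,
                duplicate_comment_flag=row.Index in dup_users,
                profile_blank_flag=blank.get(row.Index, True),
            )
        )
    result = counts.copy()
    result["behavior"] = cats
    return result


# --------------------------------------------------------------------------
# stakeholder matching

@dataclass
class StakeholderLexicon:
    """Ordered mapping stakeholder type -> keyword list; last type is fallback."""

    entries: list[tuple[str, list[str]]]

    @property
    def types(self) -> list[str]:
        return [t for t, _ in self.entries]

    @property
    def fallback(self) -> str:
        return self.entries[-1][0]


def load_default_lexicon() -> StakeholderLexicon:
    """Load the packaged 11-type keyword lexicon."""
    with resources.files("echochamber.data").joinpath(
        "stakeholder_keywords.yaml"
    ).open() as fh:
        raw = yaml.safe_load(fh)
    return StakeholderLexicon(
        entries=[(e["type"], [str(k).lower() for k in e["keywords"]]) for e in raw]
    )


def match_stakeholder(profile_text: str, lexicon: StakeholderLexicon | None = None) -> str:
    """First stakeholder type whose keyword occurs in the profile text."""
    lex = lexicon or load_default_lexicon()
    text = (profile_text or "").lower()
    for stype, keywords in lex.entries:
        if any(kw in text for kw in keywords):
            return stype
    return lex.fallback


def match_all(corpus, lexicon: StakeholderLexicon | None = None) -> pd.Series:
    """Stakeholder type per user from their profile text."""
    lex = lexicon or load_default_lexicon()
    return pd.Series(
        [match_stakeholder(t, lex) for t in corpus.users["profile_text"]],
        index=pd.Index(corpus.users["user_id"], name="user_id"),
        name="stakeholder_type",
    )
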