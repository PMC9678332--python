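"""Seeded synthetic corpus generator with planted homophily.

The generator emulates the statistical structure of a vaccine-discourse
corpus scraped from a microblogging platform: a skewed 13-topic distribution,
a three-way attitude distribution, heavy-tailed per-user activity driven by
behavior archetypes (speakers, retweeters, isolators, ...), and — crucially —
tunable homophily in interaction-partner choice.

Partner choice follows a memoryless mixture rule: when a user initiates a
retweet or comment, with probability ``h`` the target is constrained to share
the user's attribute (attitude for the user layer, home topic for the
information layer), and with probability ``1 - h`` the target attribute is
drawn from the population marginal.  Under this rule the categorical
assortativity of the resulting user network equals ``h`` in expectation for
*any* attribute distribution pi, because the mixing matrix is
``e_ij = pi_i (h [i==j] + (1-h) pi_j)``; see :func:`expected_assortativity`.
This closed form is what makes the generator usable as a parameter-recovery
oracle for the whole pipeline.

The attitude constraint is enforced strictly (an interaction whose target
pool is empty is dropped rather than mislabeled); the topic constraint is
relaxed first when both cannot be satisfied, so topic homophily is planted
approximately while attitude homophily is exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .corpus import Corpus, write_corpus
from .errors import ConfigurationError
from .roles import SentimentBand
from .taxonomy import ARCHETYPES, ATTITUDES, TOPICS

# Topic marginals: the three dominant topics (domestic status, foreign
# status, conspiracy) carry 24.46%, 20.40% and 16.46% of tweets; the
# remainder is spread over the other ten topics.
DEFAULT_TOPIC_PROBS: dict[str, float] = {
    "risk_of_infection": 0.035,
    "severity": 0.030,
    "effectiveness": 0.050,
    "adverse_effects": 0.050,
    "cost": 0.020,
    "fake_vaccines": 0.025,
    "safety": 0.040,
    "conspiracy": 0.1646,
    "means_of_vaccination": 0.060,
    "dos_and_donts": 0.030,
    "domestic_status": 0.2446,
    "foreign_status": 0.2040,
    "personal_experience": 0.0468,
}

# Attitude marginals (positive, negative, neutral): 42.51% of tweets
# positive, 13.12% negative, the rest neutral.
DEFAULT_ATTITUDE_PROBS: tuple[float, float, float] = (0.4251, 0.1312, 0.4437)

DEFAULT_ARCHETYPE_MIX: dict[str, float] = {
    "speaker": 0.01,
    "networker": 0.04,
    "monologist": 0.05,
    "retweeter": 0.10,
    "replicator": 0.08,
    "isolator": 0.20,
    "common": 0.52,
}

# mean (originals, retweets sent, comments sent) per archetype
DEFAULT_ACTIVITY_RATES: dict[str, tuple[float, float, float]] = {
    "speaker": (5.0, 0.2, 0.2),
    "networker": (3.0, 1.5, 1.0),
    "monologist": (4.0, 0.2, 0.3),
    "retweeter": (2.0, 4.0, 0.5),
    "replicator": (1.0, 0.3, 4.0),
    "isolator": (2.0, 0.0, 0.0),
    "common": (0.5, 0.8, 0.8),
}

DEFAULT_STAKEHOLDER_PROBS: dict[str, float] = {
    "common_personnel": 0.76,
    "we_media": 0.06,
    "traditional_media": 0.05,
    "government": 0.04,
    "common_company": 0.03,
    "hospital": 0.01,
    "platform_account": 0.005,
    "social_organization": 0.01,
    "medical_company": 0.005,
    "educational_institution": 0.015,
    "medical_personnel": 0.015,
}

# One profile phrase per stakeholder type; each contains a keyword of its own
# type and none of any earlier type, so lexicon matching recovers the type.
_PROFILE_PHRASES: dict[str, str] = {
    "government": "municipal government office",
    "hospital": "city hospital staff account",
    "traditional_media": "province daily newspaper",
    "we_media": "independent blogger",
    "platform_account": "sina weibo official",
    "social_organization": "health association",
    "medical_company": "vaccine manufacturer sinovac",
    "common_company": "trading company",
    "educational_institution": "high school office",
    "medical_personnel": "respiratory doctor",
    "common_personnel": "ordinary netizen",
}


def _check_probs(name: str, probs, n: int) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if arr.shape != (n,):
        raise ConfigurationError(f"{name} must have length {n}, got shape {arr.shape}")
    if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must be non-negative and sum to 1 (got sum={arr.sum()!r})")
    return arr


@dataclass
class GeneratorConfig:
    """Everything that determines a synthetic corpus, plus the seed.

    ``topic_probs`` follows the order of :data:`echochamber.taxonomy.TOPICS`;
    ``attitude_probs`` is (positive, negative, neutral).  ``h_topic`` and
    ``h_attitude`` are the planted homophily strengths in [0, 1].
    ``activity_dispersion`` is the log-scale sigma of the per-user lognormal
    frailty that multiplies archetype mean rates, producing heavy-tailed
    activity; ``label_fidelity`` is the probability that a tweet's sentiment
    score falls in the band of its author's latent attitude.
    """

    n_users: int = 2000
    topic_probs: tuple[float, ...] = tuple(DEFAULT_TOPIC_PROBS[t] for t in TOPICS)
    attitude_probs: tuple[float, float, float] = DEFAULT_ATTITUDE_PROBS
    h_topic: float = 0.3
    h_attitude: float = 0.3
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_MIX)
    )
    activity_rates: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_RATES)
    )
    stakeholder_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAKEHOLDER_PROBS)
    )
    label_fidelity: float = 1.0
    activity_dispersion: float = 1.0
    speaker_popularity: float = 30.0
    networker_popularity: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ConfigurationError("n_users must be >= 1")
        self.topic_probs = tuple(
            float(x) for x in _check_probs("topic_probs", self.topic_probs, len(TOPICS))
        )
        self.attitude_probs = tuple(
            float(x) for x in _check_probs("attitude_probs", self.attitude_probs, 3)
        )
        for h, name in ((self.h_topic, "h_topic"), (self.h_attitude, "h_attitude")):
            if not 0.0 <= h <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {h}")
        if not 0.0 <= self.label_fidelity <= 1.0:
            raise ConfigurationError("label_fidelity must lie in [0, 1]")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ConfigurationError(f"unknown archetype(s) in archetype_mix: {sorted(unknown)}")
        fr = np.array(list(self.archetype_mix.values()), dtype=float)
        if (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
            raise ConfigurationError("archetype_mix fractions must be non-negative and sum to 1")
        for arch, rates in self.activity_rates.items():
            if any(r < 0 for r in rates):
                raise ConfigurationError(f"negative activity rate for archetype {arch!r}: {rates}")
        sp = np.array(list(self.stakeholder_probs.values()), dtype=float)
        if (sp < 0).any() or abs(sp.sum() - 1.0) > 1e-9:
            raise ConfigurationError("stakeholder_probs must be non-negative and sum to 1")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["topic_probs"] = list(d["topic_probs"])
        d["attitude_probs"] = list(d["attitude_probs"])
        d["activity_rates"] = {k: list(v) for k, v in d["activity_rates"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "activity_rates" in d:
            d["activity_rates"] = {k: tuple(v) for k, v in d["activity_rates"].items()}
        for key in ("topic_probs", "attitude_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def expected_assortativity(h: float) -> float:
    """Expected assortativity of a network generated with homophily ``h``.

    Under the mixture rule the diagonal of the mixing matrix is
    ``e_ii = pi_i (h + (1-h) pi_i)`` and the off-diagonal is
    ``e_ij = (1-h) pi_i pi_j``, with both marginals equal to ``pi``.  Then

        r = (sum_i e_ii - sum_i pi_i^2) / (1 - sum_i pi_i^2)
          = (h + (1-h) s - s) / (1 - s)          with s = sum_i pi_i^2
          = h (1 - s) / (1 - s) = h,

    independently of the category distribution pi.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"homophily must lie in [0, 1], got {h}")
    return float(h)


def generate_users(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the user table with latent attitude, archetype and home topic.

    Returns a frame with the public columns (user_id, stakeholder_type,
    profile_text) plus the latent columns ``attitude``, ``archetype`` and
    ``home_topic`` used by :func:`generate_corpus` and by recovery tests.
    """
    n = config.n_users
    user_ids = [f"u{i:06d}" for i in range(n)]
    attitudes = rng.choice(ATTITUDES, size=n, p=list(config.attitude_probs))
    arch_names = list(config.archetype_mix)
    archetypes = rng.choice(arch_names, size=n, p=list(config.archetype_mix.values()))
    home_topics = rng.choice(TOPICS, size=n, p=list(config.topic_probs))
    st_names = list(config.stakeholder_probs)
    stakeholders = rng.choice(st_names, size=n, p=list(config.stakeholder_probs.values()))
    return pd.DataFrame(
        {
            "user_id": pd.array(user_ids, dtype="string"),
            "stakeholder_type": pd.array(stakeholders, dtype="string"),
            "profile_text": pd.array(
                [_PROFILE_PHRASES[s] for s in stakeholders], dtype="string"
            ),
            "attitude": attitudes,
            "archetype": archetypes,
            "home_topic": home_topics,
        }
    )


_BAND = SentimentBand()  # alpha bands follow the default classifier band


def _draw_alpha(label: str, fidelity: float, rng: np.random.Generator) -> float:
    if fidelity < 1.0 and rng.random() >= fidelity:
        label = rng.choice([a for a in ATTITUDES if a != label])
    lo_margin = 0.02
    if label == "negative":
        lo, hi = lo_margin, _BAND.neg_max - 0.02
    elif label == "positive":
        lo, hi = _BAND.pos_min + 0.02, 1.0 - lo_margin
    else:
        lo, hi = _BAND.neg_max + 0.02, _BAND.pos_min - 0.02
    return float(rng.uniform(lo, hi))


def generate_corpus(
    users: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> Corpus:
    """Generate the tweets table for a user table drawn by :func:`generate_users`.

    Originals carry the author's home topic; retweet/comment targets are
    chosen by the h-mixture rule, independently for attitude and topic, among
    all earlier tweets (so reply chains of any depth arise naturally).
    Isolator-archetype users neither send interactions nor appear as targets.
    """
    if users.empty:
        raise ConfigurationError("users table is empty")
    for col in ("attitude", "archetype", "home_topic"):
        if col not in users.columns:
            raise ConfigurationError(
                f"users table lacks latent column {col!r}; use generate_users() output"
            )

    n = len(users)
    u_att = users["attitude"].to_numpy()
    u_arch = users["archetype"].to_numpy()
    u_topic = users["home_topic"].to_numpy()
    u_id = users["user_id"].to_numpy()

    frailty = rng.lognormal(
        mean=-config.activity_dispersion**2 / 2.0,
        sigma=config.activity_dispersion,
        size=n,
    )
    rates = np.array(
        [config.activity_rates.get(a, (0.0, 0.0, 0.0)) for a in u_arch], dtype=float
    )
    n_orig = rng.poisson(rates[:, 0] * frailty)
    n_ret = rng.poisson(rates[:, 1] * frailty)
    n_com = rng.poisson(rates[:, 2] * frailty)
    is_isolator = u_arch == "isolator"
    n_ret[is_isolator] = 0
    n_com[is_isolator] = 0

    popularity = np.ones(n)
    popularity[u_arch == "speaker"] = config.speaker_popularity
    popularity[u_arch == "networker"] = config.networker_popularity

    # flat tweet store, appended in creation order
    tw_id: list[str] = []
    tw_author: list[int] = []
    tw_kind: list[str] = []
    tw_parent: list[str | None] = []
    tw_root: list[str] = []
    tw_topic: list[str] = []
    tw_alpha: list[float] = []

    # candidate-target buckets keyed by (author attitude, root topic);
    # isolators' tweets are never entered, so they receive no interactions
    buckets: dict[tuple[str, str], list[int]] = {}

    def add_tweet(author: int, kind: str, parent: str | None, root_idx: int | None) -> int:
        idx = len(tw_id)
        prefix = {"original": "o", "retweet": "r", "comment": "c"}[kind]
        tid = f"{prefix}{idx:07d}"
        topic = tw_topic[root_idx] if root_idx is not None else u_topic[author]
        tw_id.append(tid)
        tw_author.append(author)
        tw_kind.append(kind)
        tw_parent.append(parent)
        tw_root.append(tw_root[root_idx] if root_idx is not None else tid)
        tw_topic.append(topic)
        tw_alpha.append(_draw_alpha(u_att[author], config.label_fidelity, rng))
        if not is_isolator[author]:
            buckets.setdefault((u_att[author], topic), []).append(idx)
        return idx

    for u in range(n):
        for _ in range(n_orig[u]):
            add_tweet(u, "original", None, None)

    att_list = list(ATTITUDES)
    att_p = list(config.attitude_probs)
    topic_list = list(TOPICS)
    topic_p = list(config.topic_probs)

    events = [(u, "retweet") for u in range(n) for _ in range(n_ret[u])]
    events += [(u, "comment") for u in range(n) for _ in range(n_com[u])]
    order = rng.permutation(len(events))

    for ev in order:
        u, kind = events[ev]
        want_att = u_att[u] if rng.random() < config.h_attitude else att_list[
            rng.choice(3, p=att_p)
        ]
        want_topic = u_topic[u] if rng.random() < config.h_topic else topic_list[
            rng.choice(len(topic_list), p=topic_p)
        ]
        cand = [i for i in buckets.get((want_att, want_topic), []) if tw_author[i] != u]
        if not cand:
            # relax the topic constraint first: the attitude constraint is
            # the one the recovery oracle depends on
            cand = [
                i
                for t in topic_list
                for i in buckets.get((want_att, t), [])
                if tw_author[i] != u
            ]
        if not cand:
            continue  # drop the event rather than mislabel the target
        if kind == "retweet":
            w = popularity[[tw_author[i] for i in cand]]
            target = cand[rng.choice(len(cand), p=w / w.sum())]
        else:
            target = cand[rng.choice(len(cand))]
        add_tweet(u, kind, tw_id[target], _root_index(tw_root, tw_id, target))

    tweets = pd.DataFrame(
        {
            "tweet_id": pd.array(tw_id, dtype="string"),
            "author_id": pd.array([u_id[a] for a in tw_author], dtype="string"),
            "kind": pd.array(tw_kind, dtype="string"),
            "parent_id": pd.array(tw_parent, dtype="string"),
            "root_original_id": pd.array(tw_root, dtype="string"),
            "topic": pd.array(tw_topic, dtype="string"),
            "alpha": np.array(tw_alpha, dtype=float),
        }
    )
    public_users = users[["user_id", "stakeholder_type", "profile_text"]].copy()
    return Corpus(users=public_users, tweets=tweets)


def _root_index(tw_root: list[str], tw_id: list[str], target: int) -> int:
    # the root id of `target` is already resolved; map it back to its index
    root_id = tw_root[target]
    # roots are originals created before any interaction referencing them,
    # and original ids encode their index
    return int(root_id[1:])


def generate(config: GeneratorConfig) -> tuple[Corpus, pd.DataFrame]:
    """One-call generation: returns (corpus, user table with latent columns)."""
    rng = np.random.default_rng(config.seed)
    users = generate_users(config, rng)
    corpus = generate_corpus(users, config, rng)
    return corpus, users


def save_generated(
    corpus: Corpus, config: GeneratorConfig, outdir: str | Path
) -> None:
    """Write users.csv / tweets.csv plus a JSON provenance sidecar with the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_corpus(corpus, outdir / "users.csv", outdir / "tweets.csv")
    prov = dataclasses.asdict(config)
    prov["topic_probs"] = list(prov["topic_probs"])
    prov["attitude_probs"] = list(prov["attitude_probs"])
    prov["activity_rates"] = {k: list(v) for k, v in prov["activity_rates"].items()}
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2))
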