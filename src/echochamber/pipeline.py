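"""Key-user detection, echoer/bridger coding, association and chi-square
statistics, and the end-to-end report.

Opinion leaders are users in the top tail of both weighted in-degree and
local clustering on the global user network — information hubs embedded in
tight neighborhoods.  Structural hole spanners are the *other* users in the
bottom tail of Burt's constraint — brokers between otherwise disconnected
groups.  Percentile cuts are rank-based with boundary ties included, so the
detected sets are deterministic.

Echoers vs bridgers: a user whose labeled activity spans exactly one topic
is a topic-based echoer, otherwise a bridger; a user all of whose interaction
partners (authors of the tweets they retweeted/commented) share the user's
own attitude is an attitude-based echoer — vacuously so when they never
interacted — otherwise a bridger.

Association between the two role dimensions is summarized per key-user group
by support (joint count over group size) and confidence (joint count over
topic-role count), and group differences by Pearson chi-square tests with
adjusted standardized residuals and Bonferroni-corrected posthoc flags.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Corpus
from .errors import DegenerateTableError, EmptyCorpusError, UndefinedRoleError
from .holes import sh_table
from .mixing import attribute_assortativity, node_degrees, topology_summary
from .networks import build_info_network, build_user_network
from .roles import SentimentBand, classify_all, match_all, user_attitudes
from .taxonomy import MODES


@dataclass
class KeyUserConfig:
    """Percentile cuts for key-user detection (rank-based, ties included)."""

    leader_percentile: float = 5.0
    spanner_percentile: float = 5.0
    leader_rule: str = "intersection"  # or "union"

    def __post_init__(self) -> None:
        for p in (self.leader_percentile, self.spanner_percentile):
            if not 0.0 < p <= 50.0:
                raise ValueError(f"percentiles must lie in (0, 50], got {p}")
        if self.leader_rule not in ("intersection", "union"):
            raise ValueError(f"leader_rule must be intersection or union, got {self.leader_rule!r}")


def _top_cut(values: pd.Series, percentile: float) -> set:
    """Members of the top `percentile`% by value; boundary ties included."""
    n = len(values)
    k = max(1, math.ceil(n * percentile / 100.0))
    threshold = values.sort_values(ascending=False).iloc[k - 1]
    return set(values.index[values >= threshold])


def _bottom_cut(values: pd.Series, percentile: float) -> set:
    n = len(values)
    k = max(1, math.ceil(n * percentile / 100.0))
    threshold = values.sort_values(ascending=True).iloc[k - 1]
    return set(values.index[values <= threshold])


def detect_opinion_leaders(metrics: pd.DataFrame, cfg: KeyUserConfig = KeyUserConfig()) -> set:
    """Users in the top tail of weighted in-degree and local clustering.

    ``metrics`` is the :func:`echochamber.mixing.node_degrees` table.  Under
    the default intersection rule a leader must clear both cuts, which yields
    far fewer users than either cut alone.
    """
    if metrics.empty:
        raise EmptyCorpusError("empty metrics table")
    top_deg = _top_cut(metrics["weighted_in_degree"], cfg.leader_percentile)
    top_clu = _top_cut(metrics["clustering"], cfg.leader_percentile)
    return top_deg & top_clu if cfg.leader_rule == "intersection" else top_deg | top_clu


def detect_spanners(
    sh: pd.DataFrame, leaders: set, cfg: KeyUserConfig = KeyUserConfig()
) -> set:
    """Non-leader users in the bottom tail of constraint.

    ``sh`` is the :func:`echochamber.holes.sh_table` frame (isolated nodes
    already excluded there, so isolators can never become spanners).
    """
    if sh.empty:
        return set()
    return _bottom_cut(sh["constraint"], cfg.spanner_percentile) - set(leaders)


def topic_role(topics: Iterable[str]) -> str:
    """'echoer' when all of a user's labeled activity shares one topic."""
    distinct = set(topics)
    if not distinct:
        raise UndefinedRoleError("topic role undefined: no topic-labeled activity")
    return "echoer" if len(distinct) == 1 else "bridger"


def attitude_role(ego_attitude: str, partner_attitudes: Iterable[str]) -> str:
    """'echoer' when every interaction partner shares the ego's attitude.

    A user who never interacted is vacuously an echoer (isolators echo).
    """
    return (
        "echoer"
        if set(partner_attitudes) <= {ego_attitude}
        else "bridger"
    )


def user_echo_roles(
    corpus: Corpus,
    attitudes: Mapping[str, str] | pd.Series | None = None,
    band: SentimentBand = SentimentBand(),
) -> pd.DataFrame:
    """Topic and attitude role for every user with at least one tweet."""
    if attitudes is None:
        attitudes = user_attitudes(corpus, band)
    tweets = corpus.tweets
    topics_by_user = tweets.groupby("author_id")["topic"].agg(lambda s: set(s.dropna()))
    parent_author = tweets.set_index("tweet_id")["author_id"]
    inter = corpus.interactions
    partner = inter["parent_id"].map(parent_author)
    partners_by_user = (
        pd.DataFrame({"author_id": inter["author_id"], "partner": partner})
        .dropna()
        .groupby("author_id")["partner"]
        .agg(list)
    )
    rows = {}
    for user, topics in topics_by_user.items():
        partner_atts = [
            attitudes.get(p)
            for p in partners_by_user.get(user, [])
            if attitudes.get(p) is not None
        ]
        rows[user] = {
            "topic_role": topic_role(topics),
            "attitude_role": attitude_role(attitudes.get(user), partner_atts),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "user_id"
    return out


@dataclass
class AssociationResult:
    group: str
    n_total: int
    n_antecedent: int
    n_joint: int

    @property
    def support(self) -> float:
        return self.n_joint / self.n_total if self.n_total else float("nan")

    @property
    def confidence(self) -> float:
        return self.n_joint / self.n_antecedent if self.n_antecedent else float("nan")


def association_rules(
    groups: Mapping[str, Iterable],
    roles: pd.DataFrame,
    direction: str,
) -> list[AssociationResult]:
    """Support/confidence of "topic-based role => attitude-based role".

    For each group of users (plus a pooled ``Total`` row): ``n_antecedent``
    counts members whose topic role equals ``direction`` (echoer or bridger),
    ``n_joint`` those with both roles equal to it.  support = joint / total;
    confidence = joint / antecedent (NaN marker when the antecedent is empty).
    """
    if direction not in ("echoer", "bridger"):
        raise ValueError(f"direction must be 'echoer' or 'bridger', got {direction!r}")
    out = []
    pooled_total = pooled_ant = pooled_joint = 0
    for name, members in groups.items():
        members = [m for m in members]
        sub = roles.loc[roles.index.intersection(members)]
        n_total = len(members)
        n_ant = int((sub["topic_role"] == direction).sum())
        n_joint = int(
            ((sub["topic_role"] == direction) & (sub["attitude_role"] == direction)).sum()
        )
        out.append(AssociationResult(name, n_total, n_ant, n_joint))
        pooled_total += n_total
        pooled_ant += n_ant
        pooled_joint += n_joint
    out.append(AssociationResult("Total", pooled_total, pooled_ant, pooled_joint))
    return out


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    expected: np.ndarray
    adjusted_residuals: np.ndarray
    posthoc_significant: np.ndarray  # Bonferroni-corrected two-sided flags

    def pvalue_display(self, floor: float = 1e-15) -> str:
        return f"<{floor:g}" if self.pvalue < floor else f"{self.pvalue:.3g}"


def chi_square_test(table: np.ndarray | list, alpha: float = 0.05) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction.

    Posthoc: adjusted standardized residuals
    ``(O - E) / sqrt(E (1 - row/n) (1 - col/n))`` flagged significant when
    their two-sided normal p-value clears a Bonferroni correction over all
    cells.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError(f"need an r x c table with r, c >= 2, got shape {obs.shape}")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise DegenerateTableError("contingency table has a zero row or column marginal")
    total = obs.sum()
    res = stats.chi2_contingency(obs, correction=False)
    expected = res.expected_freq
    adj = (obs - expected) / np.sqrt(
        expected * (1 - row[:, None] / total) * (1 - col[None, :] / total)
    )
    cell_p = 2 * stats.norm.sf(np.abs(adj))
    posthoc = cell_p < alpha / obs.size
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        pvalue=float(res.pvalue),
        expected=expected,
        adjusted_residuals=adj,
        posthoc_significant=posthoc,
    )


# --------------------------------------------------------------------------
# end-to-end run

@dataclass
class PipelineConfig:
    band: SentimentBand = field(default_factory=SentimentBand)
    key_users: KeyUserConfig = field(default_factory=KeyUserConfig)
    weighted_assortativity: bool = True


def _association_rows(results: list[AssociationResult]) -> list[dict]:
    return [
        {
            "group": r.group,
            "n_total": r.n_total,
            "n_antecedent": r.n_antecedent,
            "n_joint": r.n_joint,
            "support": round(r.support, 3) if r.n_total else None,
            "confidence": round(r.confidence, 3) if r.n_antecedent else None,
        }
        for r in results
    ]


def run_pipeline(corpus: Corpus, config: PipelineConfig = PipelineConfig()) -> dict:
    """Run every stage on a corpus and collect a JSON-serializable report.

    The report contains, per layer (information / user) and mode (retweet /
    comment / global): topology summaries and weighted + unweighted
    assortativity; plus behavior/stakeholder/attitude tallies, key-user sets
    under both leader rules, echo-role tallies, association tables for the
    echoer and bridger directions, and the chi-square comparisons of leader
    vs spanner role composition.  Deterministic for a fixed corpus and
    config; modes with no interactions are flagged empty rather than failing.
    """
    if corpus.tweets.empty:
        raise EmptyCorpusError("corpus has no tweets")
    attitudes = user_attitudes(corpus, config.band)

    report: dict = {"networks": {}, "n_users": int(len(corpus.users))}
    graphs = {}
    for layer in ("information", "user"):
        report["networks"][layer] = {}
        for mode in MODES:
            if layer == "information":
                g = build_info_network(corpus, mode)
                attr = "topic"
            else:
                g = build_user_network(corpus, mode, attitudes=attitudes, band=config.band)
                attr = "attitude"
            graphs[(layer, mode)] = g
            entry: dict = {}
            if g.number_of_edges() == 0:
                entry["empty"] = True
                top = topology_summary(g) if g.number_of_nodes() else None
                if top is not None:
                    entry["topology"] = top.__dict__
            else:
                entry["empty"] = False
                entry["topology"] = topology_summary(g).__dict__
                for weighted, key in ((True, "weighted"), (False, "unweighted")):
                    res = attribute_assortativity(g, attr, weighted=weighted)
                    entry.setdefault("assortativity", {})[key] = {
                        "r": res.r,
                        "degenerate": res.degenerate,
                    }
            report["networks"][layer][mode] = entry

    behavior = classify_all(corpus)
    stakeholders = match_all(corpus)
    report["roles"] = {
        "behavior_counts": behavior["behavior"].value_counts().to_dict(),
        "stakeholder_counts": stakeholders.value_counts().to_dict(),
        "attitude_counts": attitudes.value_counts().to_dict(),
    }

    guser = graphs[("user", "global")]
    metrics = node_degrees(guser)
    sh, isolated = sh_table(guser)
    leaders = detect_opinion_leaders(metrics, config.key_users)
    spanners = detect_spanners(sh, leaders, config.key_users)
    # the leader definition (intersection vs union of the two cuts) is a
    # modeling choice; both set sizes are reported for transparency
    rule_sizes = {
        rule: len(
            detect_opinion_leaders(
                metrics,
                KeyUserConfig(
                    config.key_users.leader_percentile,
                    config.key_users.spanner_percentile,
                    rule,
                ),
            )
        )
        for rule in ("intersection", "union")
    }
    report["key_users"] = {
        "leaders": sorted(leaders),
        "spanners": sorted(spanners),
        "n_leaders": len(leaders),
        "n_spanners": len(spanners),
        "n_isolated_excluded": len(isolated),
        "leader_rule_sizes": rule_sizes,
    }

    roles_df = user_echo_roles(corpus, attitudes=attitudes, band=config.band)
    report["echo_roles"] = {
        "topic": roles_df["topic_role"].value_counts().to_dict(),
        "attitude": roles_df["attitude_role"].value_counts().to_dict(),
    }

    groups = {"Opinion leader": sorted(leaders), "Structural hole spanner": sorted(spanners)}
    report["association"] = {
        direction: _association_rows(association_rules(groups, roles_df, direction))
        for direction in ("echoer", "bridger")
    }

    report["chi_square"] = {}

    def _role_table(role_col: str) -> np.ndarray | None:
        rows = []
        for members in groups.values():
            sub = roles_df.loc[roles_df.index.intersection(members), role_col]
            rows.append([int((sub == "bridger").sum()), int((sub == "echoer").sum())])
        t = np.array(rows)
        if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
            return None
        return t

    for role_col, key in (("topic_role", "topic_bridger"), ("attitude_role", "attitude_bridger")):
        t = _role_table(role_col)
        if t is None:
            report["chi_square"][key] = {"degenerate": True}
            continue
        res = chi_square_test(t)
        report["chi_square"][key] = {
            "table": t.tolist(),
            "statistic": res.statistic,
            "df": res.df,
            "pvalue": res.pvalue,
            "pvalue_display": res.pvalue_display(),
        }

    # behavior-category composition of leaders vs spanners
    beh = behavior["behavior"]
    comp = pd.DataFrame(
        {
            name: beh.loc[beh.index.intersection(members)].value_counts()
            for name, members in groups.items()
        }
    ).fillna(0).astype(int)
    comp = comp.loc[(comp.sum(axis=1) > 0)]
    report["behavior_by_keyuser"] = comp.to_dict()
    if comp.shape[0] >= 2 and (comp.sum(axis=0) > 0).all():
        res = chi_square_test(comp.to_numpy().T)
        report["chi_square"]["behavior_by_keyuser"] = {
            "categories": comp.index.tolist(),
            "statistic": res.statistic,
            "df": res.df,
            "pvalue": res.pvalue,
            "pvalue_display": res.pvalue_display(),
        }
    return report


def save_report(report: dict, outdir: str | Path) -> None:
    """Serialize the report as report.json plus flat CSV extracts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    rows = []
    for layer, modes in report["networks"].items():
        for mode, entry in modes.items():
            row = {"layer": layer, "mode": mode, "empty": entry.get("empty")}
            row.update(entry.get("topology", {}))
            for key in ("weighted", "unweighted"):
                a = entry.get("assortativity", {}).get(key)
                row[f"r_{key}"] = a["r"] if a else None
            rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "networks.csv", index=False)
    for direction in ("echoer", "bridger"):
        pd.DataFrame(report["association"][direction]).to_csv(
            outdir / f"association_{direction}.csv", index=False
        )
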