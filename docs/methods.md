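# Methods

## Problem setting

The package analyzes interaction corpora from microblogging platforms in
which users post originals, retweet and comment, each original carries one
of 13 topics from a Health Belief Model coding scheme (perceived
susceptibility/severity, benefits, barriers, cues to action), and every
tweet carries a sentiment positive-probability α ∈ [0, 1] produced upstream
by a sentiment model (the package never infers sentiment itself).  The
question is whether interaction is homophilous — an *echo chamber* — along
two dimensions: the topics users engage with, and the attitudes of the users
they engage with; and which users (opinion leaders, structural hole
spanners) reinforce or bridge these chambers.

## Networks

**Information representational network** (per mode retweet / comment /
global): undirected, nodes are original tweets labeled by topic, and the
weight of edge (i, j) is the number of *distinct* users who interacted with
both i and j through the mode's relation, interactions being attributed to
the root original of the reply chain.  Counting distinct users (not events)
follows the definition of "common users"; consequently the global layer's
weights are *not* the sum of the retweet and comment layers' (a user may
reach i by retweet and j by comment), only bounded below by each — the user
network, whose weights are event counts, does partition exactly.

**User communication flow network**: directed, nodes are users labeled by
attitude, and edge i→j counts the interactions in which i's retweet/comment
has a parent tweet authored by j.  The credited partner is the author of the
*immediate* parent, not the root original's author: retweeting a retweet is
an interaction with the re-poster.  Self-interactions are dropped (self-loops
corrupt clustering and constraint conventions).  Authors with no interaction
in the chosen mode remain as isolated nodes by default (`include_isolated_
authors`), since isolated users are analytically interesting here.

## Echo chamber quantification

Newman's categorical assortativity r is computed from the mixing matrix of
edge-weight fractions; undirected edges contribute half their weight to each
orientation.  Weights enter as multiplicities by default because the
networks are weighted by construction; a `weighted=False` flag binarizes,
and the pipeline reports both variants since either convention is
defensible.  A single-category graph makes the denominator vanish; the
result is then flagged `degenerate` (r reported as 0) rather than raising.

Topology summaries use unweighted edge counts: density, average local
clustering (undirected unweighted projection, degree-<2 nodes contributing
0 — deterministic and the common tool default), transitivity on the same
projection, and reciprocity for directed graphs only (a `None` marker
otherwise).

## Structural holes

Burt's indices are computed on symmetrized tie strengths z′ᵢⱼ = zᵢⱼ + zⱼᵢ,
following the original formulation and the conventions of the classic
UCINET-style tools: proportional tie strengths pᵢⱼ, dyadic constraint
cᵢⱼ = (pᵢⱼ + Σ_q pᵢ_q p_qⱼ)² with q over the ego's other contacts,
effective size S = N − Σⱼ Σ_q pᵢ_q mⱼ_q with mⱼ_q = z′ⱼ_q / max_k z′ⱼ_k,
efficiency S/N, and hierarchy as the Coleman–Theil concentration of the
cᵢⱼ (0 when constraints are evenly spread, defined as 0 for N = 1).
Aggregate constraint may exceed 1 for small interlocked ego networks
(triangle node: C = 1.125); descriptions of constraint as lying "between 0
and 1" are informal and no clamping is applied.  Isolated egos have all four
indices undefined and are excluded from batch tables (and hence from
spanner candidacy).

## User classification

*Sentiment*: α is banded into negative (α ≤ 0.4), neutral, positive
(α ≥ 0.6).  Published threshold rules for such α scores are often printed
inconsistently; a symmetric band around 0.5 keeps three classes
deterministic and is exposed as `SentimentBand`.  A user's attitude is the
modal label of their tweets, ties resolving to neutral (a tied user
expresses no dominant stance).

*Behavior taxonomy*: ten categories assigned by first match in the
precedence automatic → isolator → high/medium/low speaker → networker →
monologist → retweeter → replicator → common.  The criteria are not mutually
exclusive, so a fixed precedence (most specific first, influentials before
broadcasters) is required for a single-label contract.  Speaker tiers read
"x times higher" as ratio ≥ x of retweets received to originals posted
(≥ 100 / 10 / 3); "number of tweets" means originals only, distinct from
retweets/comments sent; population means include zero-count users; any
ratio with a zero denominator evaluates false instead of raising.

*Stakeholder type*: case-insensitive substring matching of an ordered
11-type keyword lexicon (government, hospital, traditional media, We-media,
platform account, social organization, medical company, common company,
educational institution, medical personnel) against the profile text; the
first type with a hit wins and `common_personnel` is the keywordless
fallback.  The lexicon ships as editable YAML.

## Key users and echo roles

Opinion leaders: intersection of the top-5% sets (rank-based cut, boundary
ties included) of weighted in-degree and local clustering on the global user
network.  The intersection reading is adopted because a combined requirement
yields the "far fewer than either cut" leader counts reported for real
corpora; the union size is also emitted for transparency.  Structural hole
spanners: bottom 5% of constraint among all non-isolated users, computed
first, then leaders removed — so the two sets are disjoint by construction
and isolators can be neither.

Topic role: a user whose created/retweeted/commented tweets span exactly one
topic is an echoer, otherwise a bridger.  Attitude role: a user all of whose
interaction partners share the user's own attitude is an echoer — vacuously
including users who never interacted — otherwise a bridger.  The
ego-anchored reading (partners must match the *ego's* attitude) is adopted
because it makes isolated users echoers, which is the behavior the role
definitions intend.

Association between the two dimensions is summarized per key-user group and
pooled: support = joint count / group size, confidence = joint count /
topic-side antecedent count (an undefined marker when the antecedent is
empty); three-decimal rounding is applied only at report boundaries.  Group
comparisons use Pearson χ² without continuity correction, with adjusted
standardized residuals (O − E)/√(E(1 − rᵢ/n)(1 − cⱼ/n)) and Bonferroni
correction over cells as the posthoc; p-values below 1e−15 are displayed as
upper bounds.

## Synthetic corpus generator

The generator is the package's test bed and defines the conditions under
which the pipeline's guarantees are stated.  Each user draws a latent
attitude (defaults 42.51% positive / 13.12% negative / 44.37% neutral), a
home topic (top three topics at 24.46% / 20.40% / 16.46%, remainder spread
over ten topics), a behavior archetype (isolators 20%, common 52%, the rest
split among speakers, networkers, monologists, retweeters, replicators) and
a stakeholder type whose profile phrase contains a matching lexicon keyword.
Activity counts are Poisson with archetype-specific means multiplied by a
per-user lognormal frailty (σ = 1, mean 1), giving heavy-tailed activity;
the tail shape is a free modeling choice since only aggregate shares are
published for real corpora.

Partner choice is per-interaction and memoryless: with probability
h_attitude the target's author must share the initiator's attitude,
otherwise the target attitude is drawn from the marginal; independently the
root topic is constrained with probability h_topic.  Candidates are all
earlier tweets (so deep reply chains arise naturally), excluding the
initiator's own tweets and all isolators' tweets; speaker-authored tweets
carry a popularity multiplier (default 30×) as retweet targets so that
speaker tiers are reachable.  When both constraints cannot be met the topic
constraint is relaxed first; if no same-attitude target exists the event is
dropped rather than mislabeled.  Attitude homophily is therefore planted
exactly and the closed form r = h holds (e_ij = πᵢ(h·1[i=j] + (1−h)πⱼ) ⇒
r = h for any π), while topic homophily is approximate.  Tweet α values are
drawn uniformly inside the band of the author's attitude (with margin, so
discretization is stable); a `label_fidelity` parameter can inject label
noise to separate sentiment-model error from network structure.

What the generator does *not* emulate: temporal dynamics, follower graphs,
content text, preferential attachment beyond archetype rate heterogeneity,
and bursty conversation structure.  Passing recovery tests therefore shows
the pipeline measures planted mixing correctly, not that real corpora obey
the mixture model.

## Numerical and scale choices

Determinism: all randomness flows through one `numpy` Generator seeded from
the config; identical (config, seed) reproduces the corpus byte-identically,
and the corpus CSV roundtrip is bit-exact (α written as `%.17g`, parsed with
`float`).  Validation reports violations as data rather than exceptions.
Oracle-equivalence tests run on exhaustive small random graphs (≤ 6 nodes
for assortativity, ≤ 8 for Burt indices, tolerance 1e−9); homophily
recovery is checked at 5000 users over h ∈ {0, 0.25, 0.5, 0.75, 1} with a
±0.05 band, sizes at which the whole suite runs in seconds on one CPU.

## Known limitations

- Echo roles are binary; no continuous echoing intensity is computed.
- No community detection or network-level brokerage decompositions.
- The information-network homophily h_topic is planted only approximately
  (attitude constraints take precedence in sparse candidate pools).
- Stakeholder matching is substring-based and English-keyword shipped;
  real deployments should localize the lexicon.
- Bot detection is out of scope; the `automatic` class fires only on
  explicit duplicate-comment and blank-profile evidence.
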