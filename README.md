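# echochamber

Tools for quantifying **echo chambers** in social-media interaction data —
written for computational social scientists and public-health infodemiology
researchers studying how topics and attitudes (e.g. toward vaccines)
circulate on microblogging platforms.

Starting from a tabular corpus (a users table and a tweets table, where each
tweet is an original, retweet or comment with a topic label and a sentiment
positive-probability α), the package:

- builds the **information representational network** (undirected; nodes =
  original posts, linked by the number of distinct users who interacted with
  both) and the **user communication flow network** (directed; edge i→j
  weighted by the number of times i retweeted/commented on j's tweets), each
  in retweet / comment / global modes;
- measures homophily with **Newman's categorical assortativity**

  r = (Σᵢ eᵢᵢ − Σᵢ aᵢbᵢ) / (1 − Σᵢ aᵢbᵢ),

  where e is the matrix of edge-weight fractions between attribute
  categories (topic or attitude) and a, b its marginals — r ≈ 1 means users
  interact almost exclusively within their own group;
- computes per-node weighted degrees, local clustering, and **Burt's
  structural-hole indices** (effective size S, efficiency E = S/N,
  constraint C = Σⱼ (pᵢⱼ + Σ_q pᵢ_q p_qⱼ)², Coleman–Theil hierarchy H);
- classifies users by **behavior taxonomy** (speakers, networkers,
  monologists, retweeters, replicators, isolators, automatic, common),
  **stakeholder type** (11-type keyword lexicon) and **attitude** (modal
  sentiment of their tweets);
- detects **opinion leaders** (top tail of weighted in-degree *and* local
  clustering) and **structural hole spanners** (non-leaders in the bottom
  tail of constraint), codes every user as a topic/attitude **echoer or
  bridger**, and links the two role dimensions with association-rule
  support/confidence and Pearson χ² tests;
- ships a seeded **synthetic corpus generator** with planted homophily h in
  partner choice, for which the expected assortativity is exactly r = h —
  so the whole pipeline can be exercised and validated without any platform
  data.

## Worked example

```python
from echochamber import (GeneratorConfig, generate, build_user_network,
                         attribute_assortativity)

cfg = GeneratorConfig(n_users=2000, h_attitude=0.5, seed=7)
corpus, users = generate(cfg)
g = build_user_network(corpus, "global")      # attitudes estimated from alpha
print(attribute_assortativity(g, "attitude").r)
```

prints `0.493…`: the recovered assortativity of the user network sits next
to the planted homophily h = 0.5, because under the generator's mixture rule
(with probability h pick a same-attitude target, otherwise follow the
population marginal) the mixing matrix gives r = h for any attitude
distribution.  Running `python examples/echo_chamber_effect.py` produces the
full table:

```
layer        mode      nodes  edges  density    r
information  retweet    2669   3870  0.00109  +0.155
information  comment    2669   4241  0.00119  +0.159
information  global     2669  11306  0.00318  +0.147
user         retweet    1490   1690  0.00076  +0.233
user         comment    1490   1824  0.00082  +0.273
user         global     1490   3498  0.00158  +0.254

planted h_attitude vs recovered r (global user network):
  h = 0.00  ->  r = -0.002
  h = 0.50  ->  r = +0.493
  h = 1.00  ->  r = +1.000
```

Low positive r on sparse networks is the typical "weak echo chamber"
signature.  The other scripts in `examples/` demonstrate corpus generation
and validation, structural-hole indices on hand-sized graphs (star center
C = 1/n; triangle node C = 1.125), and the end-to-end key-user analysis with
the association table. A thin CLI mirrors the stages
(`echochamber synth|build|metrics|holes|roles|analyze`).

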