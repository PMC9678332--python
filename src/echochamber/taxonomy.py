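"""Controlled vocabularies: topics, attitudes, tweet kinds, behavior categories.

The topic vocabulary follows the Health Belief Model coding scheme commonly
used for vaccine discourse: perceived susceptibility and severity, perceived
benefits and barriers, and cues to action (self-efficacy is omitted for its
low prevalence in vaccine debates), for 13 topics in total.
"""

TOPICS: tuple[str, ...] = (
    "risk_of_infection",          # perceived susceptibility
    "severity",                   # perceived severity
    "effectiveness",              # perceived benefits
    "adverse_effects",            # perceived barriers
    "cost",
    "fake_vaccines",
    "safety",
    "conspiracy",
    "means_of_vaccination",       # cues to action
    "dos_and_donts",
    "domestic_status",
    "foreign_status",
    "personal_experience",
)

ATTITUDES: tuple[str, ...] = ("positive", "negative", "neutral")

TWEET_KINDS: tuple[str, ...] = ("original", "retweet", "comment")

MODES: tuple[str, ...] = ("retweet", "comment", "global")

BEHAVIOR_CATEGORIES: tuple[str, ...] = (
    "high_speaker",
    "medium_speaker",
    "low_speaker",
    "networker",
    "monologist",
    "retweeter",
    "replicator",
    "isolator",
    "automatic",
    "common",
)

ARCHETYPES: tuple[str, ...] = (
    "speaker",
    "networker",
    "monologist",
    "retweeter",
    "replicator",
    "isolator",
    "common",
)
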