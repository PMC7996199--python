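"""Seeded generator of attitude-labelled multi-topic interaction datasets.

The generator emulates the structure of a rumor-rebuttal corpus: a handful
of original rebuttal posts per topic, a population of users with latent
attitudes drawn from a configurable mixture, and retweet/comment cascades
whose targeting has a tunable like-minded preference λ (the echo-chamber
dial):

    with probability λ      the event targets a post by a same-attitude
                            author (selective exposure); if no such post
                            exists the event is dropped — the user finds
                            no congenial content and does not engage;
    with probability 1 - λ  the event targets a uniformly random post.

Community structure is planted: users belong to latent blocks and, within
whichever candidate pool λ selected, prefer same-block authors, so that
modularity-based community detection has real signal to find.  Block
attitudes can be coupled (``community_attitude_coupling``) to produce
attitude-homogeneous communities, the regime where echo chambers live.

Post-level attitude codes equal the latent attitude up to a configurable
noise rate, so the majority-vote aggregation is exercised nontrivially.
Token streams are sampled from the lexicon; cross-cutting events oversample
negative-polarity words by ``sentiment_shift`` (a mixture-weight change —
the scorer remains the only route from tokens to scores).  Information and
civility codes follow per-edge-type conditional probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import (
    Attitude,
    CivilityCode,
    Dataset,
    InfoCode,
    Kind,
    Post,
    SentimentLexicon,
)

__all__ = ["SimConfig", "GenerationError", "toy_lexicon", "generate", "sweep"]

_EDGE_TYPES = ("like_minded", "cross_cutting", "unclear")

_DEFAULT_TOPICS = (
    "epidemic_situation",
    "foreign_countermeasures",
    "prevention",
    "virus",
    "patients",
    "domestic_government_countermeasures",
)

_FILLERS = (
    "the", "rumor", "rebuttal", "virus", "city", "mask", "news",
    "official", "report", "today", "people", "says",
)


class GenerationError(RuntimeError):
    """The configuration cannot produce a valid dataset."""


def toy_lexicon() -> SentimentLexicon:
    """Small balanced lexicon used by the generator and the examples."""
    sentiment = {
        # positive
        "good": (1, 3), "great": (1, 5), "excellent": (1, 7), "wonderful": (1, 9),
        "fine": (1, 1), "helpful": (1, 3), "trustworthy": (1, 5), "relieved": (1, 5),
        # negative
        "bad": (-1, 3), "awful": (-1, 7), "terrible": (-1, 9), "fake": (-1, 5),
        "angry": (-1, 5), "doubtful": (-1, 1), "misleading": (-1, 3), "shameful": (-1, 7),
    }
    adverbs = {"slightly": 0.6, "fairly": 0.8, "very": 1.5, "extremely": 2.0}
    negations = frozenset({"not", "never", "no"})
    return SentimentLexicon(sentiment, adverbs, negations)


@dataclass
class SimConfig:
    """Study conditions for one synthetic corpus.

    Scalars apply to every topic.  ``attitude_mixture`` gives the latent
    attitude probabilities (agree, disagree, query, unknown); ``homophily``
    is λ in [0, 1]; ``info_probs`` maps edge type -> (P(seeking),
    P(sharing)); ``incivility_probs`` maps edge type -> P(uncivil).
    """

    seed: int = 0
    n_topics: int = 6
    topic_names: Optional[tuple[str, ...]] = None
    n_original_posters: int = 3
    n_users: int = 250
    community_count: int = 4
    attitude_mixture: dict = field(
        default_factory=lambda: {
            Attitude.AGREE: 0.60,
            Attitude.DISAGREE: 0.15,
            Attitude.QUERY: 0.10,
            Attitude.UNKNOWN: 0.15,
        }
    )
    homophily: float = 0.7
    mean_retweets: float = 1.0
    mean_comments: float = 0.5
    attitude_noise: float = 0.10
    community_attitude_coupling: float = 0.8
    within_community_pref: float = 0.85
    sentiment_shift: float = 0.25
    base_negative_rate: float = 0.55
    mean_sentiment_words: float = 2.5
    info_probs: dict = field(
        default_factory=lambda: {
            "like_minded": (0.05, 0.03),
            "cross_cutting": (0.20, 0.12),
            "unclear": (0.10, 0.06),
        }
    )
    incivility_probs: dict = field(
        default_factory=lambda: {
            "like_minded": 0.03,
            "cross_cutting": 0.15,
            "unclear": 0.06,
        }
    )
    lexicon: SentimentLexicon = field(default_factory=toy_lexicon)

    def __post_init__(self) -> None:
        self.attitude_mixture = {
            Attitude(k): float(v) for k, v in self.attitude_mixture.items()
        }
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.homophily <= 1.0):
            raise ValueError(f"homophily λ must lie in [0, 1], got {self.homophily}")
        total = sum(self.attitude_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"attitude mixture must sum to 1, got {total}")
        if any(v < 0 for v in self.attitude_mixture.values()):
            raise ValueError("attitude mixture probabilities must be >= 0")
        for name in ("n_topics", "n_original_posters", "n_users", "community_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mean_retweets", "mean_comments"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("attitude_noise", "community_attitude_coupling",
                     "within_community_pref"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for et in _EDGE_TYPES:
            ps, pr = self.info_probs[et]
            if ps < 0 or pr < 0 or ps + pr > 1:
                raise ValueError(f"info_probs[{et!r}] must be a sub-probability pair")
            if not (0.0 <= self.incivility_probs[et] <= 1.0):
                raise ValueError(f"incivility_probs[{et!r}] must lie in [0, 1]")

    def topics(self) -> tuple[str, ...]:
        if self.topic_names is not None:
            if len(self.topic_names) != self.n_topics:
                raise ValueError("topic_names length must equal n_topics")
            return tuple(self.topic_names)
        names = list(_DEFAULT_TOPICS)
        while len(names) < self.n_topics:
            names.append(f"topic_{len(names):02d}")
        return tuple(names[: self.n_topics])


def _latent_edge_type(a: Attitude, b: Attitude) -> str:
    clear = {Attitude.AGREE, Attitude.DISAGREE}
    if a not in clear or b not in clear:
        return "unclear"
    return "like_minded" if a is b else "cross_cutting"


def _sample_attitude(rng: np.random.Generator, mixture: dict) -> Attitude:
    atts = list(mixture)
    probs = np.array([mixture[a] for a in atts])
    return atts[rng.choice(len(atts), p=probs / probs.sum())]


def _sample_tokens(
    rng: np.random.Generator,
    lexicon: SentimentLexicon,
    negative_rate: float,
    mean_words: float,
) -> tuple[str, ...]:
    pos, neg = lexicon.positive_words, lexicon.negative_words
    adverbs = list(lexicon.adverb_entries)
    negations = sorted(lexicon.negation_words)
    n_sent = int(rng.poisson(mean_words))
    tokens: list[str] = [_FILLERS[int(rng.integers(len(_FILLERS)))]]
    for _ in range(n_sent):
        if rng.random() < 0.20 and negations:
            tokens.append(negations[int(rng.integers(len(negations)))])
        if rng.random() < 0.30 and adverbs:
            tokens.append(adverbs[int(rng.integers(len(adverbs)))])
        pool = neg if rng.random() < negative_rate else pos
        tokens.append(pool[int(rng.integers(len(pool)))])
        tokens.append(_FILLERS[int(rng.integers(len(_FILLERS)))])
    return tuple(tokens)


def _code_with_noise(
    rng: np.random.Generator, latent: Attitude, noise: float
) -> Attitude:
    if noise > 0 and rng.random() < noise:
        others = [a for a in Attitude if a is not latent]
        return others[int(rng.integers(len(others)))]
    return latent


def generate(config: SimConfig) -> Dataset:
    """Generate one dataset; identical configs reproduce it bit-for-bit."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    base_time = datetime(2020, 1, 23, 10, 0, 0)
    clock = 0

    def stamp() -> str:
        nonlocal clock
        clock += 1
        return (base_time + timedelta(minutes=clock)).isoformat()

    posts: list[Post] = []
    skipped = 0
    for topic in config.topics():
        # --- population -------------------------------------------------
        block_attitude = [
            _sample_attitude(rng, config.attitude_mixture)
            for _ in range(config.community_count)
        ]
        users: list[tuple[str, Attitude, int]] = []  # (id, latent, block)
        for i in range(config.n_users):
            block = int(rng.integers(config.community_count))
            if rng.random() < config.community_attitude_coupling:
                latent = block_attitude[block]
            else:
                latent = _sample_attitude(rng, config.attitude_mixture)
            users.append((f"{topic}:u{i:04d}", latent, block))

        # --- original rebuttal posts ------------------------------------
        # pool rows: (post_id, author_id, latent attitude of author, block)
        pool: list[tuple[str, str, Attitude, int]] = []
        for i in range(config.n_original_posters):
            author = f"{topic}:op{i}"
            pid = f"{topic}:orig{i}"
            posts.append(
                Post(
                    post_id=pid,
                    author_id=author,
                    timestamp=stamp(),
                    kind=Kind.ORIGINAL,
                    parent_post_id=None,
                    topic=topic,
                    tokens=_sample_tokens(
                        rng, config.lexicon, 0.3, config.mean_sentiment_words
                    ),
                    attitude_code=Attitude.AGREE,
                    info_code=InfoCode.SHARING,
                    civility_code=CivilityCode.CIVIL,
                )
            )
            pool.append((pid, author, Attitude.AGREE, int(rng.integers(config.community_count))))
        if not pool:
            raise GenerationError(f"topic {topic!r}: no targetable posts")

        # --- interaction events -----------------------------------------
        events: list[tuple[int, Kind]] = []
        for ui in range(config.n_users):
            for _ in range(int(rng.poisson(config.mean_retweets))):
                events.append((ui, Kind.RETWEET))
            for _ in range(int(rng.poisson(config.mean_comments))):
                events.append((ui, Kind.COMMENT))
        order = rng.permutation(len(events))
        counter = 0
        for ei in order:
            ui, kind = events[ei]
            user_id, latent, block = users[ui]
            candidates = [row for row in pool if row[1] != user_id]
            if not candidates:
                raise GenerationError(
                    f"topic {topic!r}: zero eligible targets for {kind.value}"
                )
            if rng.random() < config.homophily:
                candidates = [row for row in candidates if row[2] is latent]
                if not candidates:
                    skipped += 1  # no congenial content: the user disengages
                    continue
            if config.within_community_pref > 0 and rng.random() < config.within_community_pref:
                same_block = [row for row in candidates if row[3] == block]
                if same_block:
                    candidates = same_block
            target = candidates[int(rng.integers(len(candidates)))]
            et = _latent_edge_type(latent, target[2])
            p_seek, p_share = config.info_probs[et]
            draw = rng.random()
            info = (
                InfoCode.SEEKING
                if draw < p_seek
                else InfoCode.SHARING if draw < p_seek + p_share else InfoCode.NONE
            )
            uncivil = rng.random() < config.incivility_probs[et]
            neg_rate = config.base_negative_rate + (
                config.sentiment_shift if et == "cross_cutting" else 0.0
            )
            pid = f"{topic}:{kind.value[:2]}{counter:05d}"
            counter += 1
            posts.append(
                Post(
                    post_id=pid,
                    author_id=user_id,
                    timestamp=stamp(),
                    kind=kind,
                    parent_post_id=target[0],
                    topic=topic,
                    tokens=_sample_tokens(
                        rng,
                        config.lexicon,
                        float(np.clip(neg_rate, 0.0, 1.0)),
                        config.mean_sentiment_words,
                    ),
                    attitude_code=_code_with_noise(rng, latent, config.attitude_noise),
                    info_code=info,
                    civility_code=(
                        CivilityCode.UNCIVIL if uncivil else CivilityCode.CIVIL
                    ),
                )
            )
            pool.append((pid, user_id, latent, block))

    return Dataset(
        posts=posts,
        lexicon=config.lexicon,
        provenance={
            "generator": "echonets.synthetic.generate",
            "seed": config.seed,
            "homophily": config.homophily,
            "skipped_events": skipped,
        },
    )


def sweep(
    config: SimConfig,
    lambda_grid: list[float],
    replicates: int = 3,
) -> pd.DataFrame:
    """Measure echo metrics across a λ grid (one row per λ, averaged
    over replicates): pooled like-minded weighted proportion of retweet
    networks, mean community-network assortativity, mean heterogeneity.
    """
    from .echo_metrics import LIKE_MINDED, echo_report

    for lam in lambda_grid:
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"λ grid value {lam} outside [0, 1]")
    rows = []
    for li, lam in enumerate(lambda_grid):
        props, rs, hs = [], [], []
        for rep in range(replicates):
            sub_seed = (config.seed + 10_007 * li + 257 * rep) % (2**31)
            ds = generate(replace(config, seed=sub_seed, homophily=lam))
            reports = echo_report(ds, mechanisms=(Kind.RETWEET,), seed=sub_seed)
            total = sum(r.edge_summary.total for r in reports)
            like = sum(r.edge_summary.weights[LIKE_MINDED] for r in reports)
            if total > 0:
                props.append(like / total)
            rs.extend(r.assortativity for r in reports if r.assortativity is not None)
            hs.extend(
                h
                for r in reports
                for h in r.communities["H"].dropna().tolist()
            )
        rows.append(
            {
                "lam": lam,
                "like_minded_prop": float(np.mean(props)) if props else np.nan,
                "assortativity": float(np.mean(rs)) if rs else np.nan,
                "mean_H": float(np.mean(hs)) if hs else np.nan,
            }
        )
    return pd.DataFrame(rows)
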