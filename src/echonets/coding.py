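"""Preprocessing filters, user-attitude aggregation and inter-coder reliability.

Manual codes arrive on individual posts; analysis needs one attitude per
user per interaction mechanism.  The aggregation rule is majority vote over
a user's clearly coded posts (agree / disagree / query), with frequency
ties broken by the most recent post among the tied attitudes, and a fall
back to ``unknown`` when no post expresses a clear stance.  Attitudes map
to integer scores: agree = +1, disagree = -1, query / unknown = 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import Attitude, Dataset, Kind, Post

__all__ = [
    "UserAttitude",
    "ATTITUDE_SCORES",
    "attitude_score",
    "aggregate_user_attitude",
    "filter_low_impact",
    "cohen_kappa",
]

ATTITUDE_SCORES = {
    Attitude.AGREE: 1,
    Attitude.DISAGREE: -1,
    Attitude.QUERY: 0,
    Attitude.UNKNOWN: 0,
}

_CLEAR = (Attitude.AGREE, Attitude.DISAGREE, Attitude.QUERY)


@dataclass(frozen=True)
class UserAttitude:
    user_id: str
    attitude: Attitude
    score: int

    def __post_init__(self) -> None:
        expected = ATTITUDE_SCORES[self.attitude]
        if self.score != expected:
            raise ValueError(
                f"attitude {self.attitude.value!r} must score {expected}, "
                f"got {self.score}"
            )


def attitude_score(attitude: Attitude) -> int:
    """Map an attitude to its integer score (+1 / -1 / 0)."""
    return ATTITUDE_SCORES[Attitude(attitude)]


def aggregate_user_attitude(posts_of_user: Sequence[Post]) -> UserAttitude:
    """Aggregate one user's posts (one mechanism) into a single attitude.

    Majority vote over posts coded agree/disagree/query.  Ties are broken
    by the latest post *among the tied attitudes* (timestamp order, then
    input order).  If no post is clearly coded the user is ``unknown``.
    """
    posts = list(posts_of_user)
    if not posts:
        raise ValueError("user has no posts in this mechanism")
    authors = {p.author_id for p in posts}
    if len(authors) != 1:
        raise ValueError(f"posts span several authors: {sorted(authors)}")
    user_id = posts[0].author_id

    clear = [p for p in posts if p.attitude_code in _CLEAR]
    if not clear:
        return UserAttitude(user_id, Attitude.UNKNOWN, 0)

    counts = Counter(p.attitude_code for p in clear)
    top = max(counts.values())
    tied = {att for att, c in counts.items() if c == top}
    if len(tied) == 1:
        winner = next(iter(tied))
    else:
        # latest post whose code is among the tied attitudes prevails
        latest = max(
            (p for p in clear if p.attitude_code in tied),
            key=lambda p: (p.timestamp, posts.index(p)),
        )
        winner = latest.attitude_code
    return UserAttitude(user_id, winner, ATTITUDE_SCORES[winner])


def _cascade_roots(dataset: Dataset) -> dict[str, str]:
    """Map every post id to the id of the original post rooting its cascade."""
    parents = {p.post_id: p.parent_post_id for p in dataset.posts}
    roots: dict[str, str] = {}

    def root_of(pid: str) -> str:
        chain = []
        cur = pid
        while cur not in roots and parents.get(cur) is not None:
            chain.append(cur)
            cur = parents[cur]
        base = roots.get(cur, cur)
        for c in chain:
            roots[c] = base
        return base

    for p in dataset.posts:
        roots[p.post_id] = root_of(p.post_id)
    return roots


def filter_low_impact(
    dataset: Dataset, min_count: int = 20, rule: str = "either"
) -> Dataset:
    """Remove low-impact originals together with their whole cascades.

    Retweet and comment counts are taken over the full cascade rooted at
    each original.  Under ``rule="either"`` (default) an original survives
    if its retweet count *or* its comment count reaches ``min_count``;
    under ``rule="both"`` it survives only if both do.
    """
    if rule not in ("either", "both"):
        raise ValueError(f"rule must be 'either' or 'both', got {rule!r}")
    roots = _cascade_roots(dataset)
    rt_counts: Counter[str] = Counter()
    cm_counts: Counter[str] = Counter()
    for p in dataset.posts:
        if p.kind is Kind.RETWEET:
            rt_counts[roots[p.post_id]] += 1
        elif p.kind is Kind.COMMENT:
            cm_counts[roots[p.post_id]] += 1

    def survives(original_id: str) -> bool:
        rt, cm = rt_counts[original_id], cm_counts[original_id]
        if rule == "either":
            return rt >= min_count or cm >= min_count
        return rt >= min_count and cm >= min_count

    keep_roots = {
        p.post_id for p in dataset.posts if p.kind is Kind.ORIGINAL and survives(p.post_id)
    }
    kept = [p for p in dataset.posts if roots[p.post_id] in keep_roots]
    return Dataset(
        posts=kept,
        lexicon=dataset.lexicon,
        provenance={
            **dataset.provenance,
            "filter": {"min_count": min_count, "rule": rule},
        },
    )


def cohen_kappa(codes_a: Sequence, codes_b: Sequence) -> float:
    """Chance-corrected inter-coder agreement, kappa = (p_o - p_e)/(1 - p_e).

    Returns 1.0 in the degenerate case where both coders use a single
    identical label throughout (p_o = p_e = 1).
    """
    a = list(codes_a)
    b = list(codes_b)
    if len(a) != len(b):
        raise ValueError(
            f"code vectors differ in length: {len(a)} vs {len(b)}"
        )
    if not a:
        raise ValueError("code vectors are empty")
    n = len(a)
    labels = sorted({*a, *b}, key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0))) / n**2
    if p_e >= 1.0:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))
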