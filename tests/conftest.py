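from __future__ import annotations

import itertools

import pytest

from echonets.data_model import (
    Attitude,
    CivilityCode,
    Dataset,
    InfoCode,
    Kind,
    Post,
    SentimentLexicon,
)

_counter = itertools.count()


def make_post(
    post_id=None,
    author="u1",
    timestamp=None,
    kind=Kind.RETWEET,
    parent="orig1",
    topic="virus",
    tokens=(),
    attitude=Attitude.AGREE,
    info=InfoCode.NONE,
    civility=CivilityCode.CIVIL,
) -> Post:
    i = next(_counter)
    if post_id is None:
        post_id = f"p{i}"
    if timestamp is None:
        timestamp = f"2020-02-01T10:{i % 60:02d}:{(i // 60) % 60:02d}"
    kind = Kind(kind)
    return Post(
        post_id=post_id,
        author_id=author,
        timestamp=timestamp,
        kind=kind,
        parent_post_id=None if kind is Kind.ORIGINAL else parent,
        topic=topic,
        tokens=tuple(tokens),
        attitude_code=Attitude.AGREE if kind is Kind.ORIGINAL else Attitude(attitude),
        info_code=InfoCode(info),
        civility_code=CivilityCode(civility),
    )


def make_original(post_id="orig1", author="op1", topic="virus", **kw) -> Post:
    return make_post(post_id=post_id, author=author, kind=Kind.ORIGINAL,
                     parent=None, topic=topic, **kw)


@pytest.fixture
def tiny_lexicon() -> SentimentLexicon:
    return SentimentLexicon(
        sentiment_entries={
            "good": (1, 3),
            "great": (1, 5),
            "excellent": (1, 7),
            "bad": (-1, 3),
            "awful": (-1, 7),
            "fake": (-1, 5),
        },
        adverb_entries={"very": 1.5, "slightly": 0.6, "extremely": 2.0},
        negation_words=frozenset({"not", "never"}),
    )


@pytest.fixture
def small_dataset() -> Dataset:
    """One topic, one original, a few retweets and comments."""
    posts = [make_original()]
    for u, att in (("a1", "agree"), ("a2", "agree"), ("d1", "disagree")):
        posts.append(make_post(author=u, attitude=att, parent="orig1"))
    posts.append(make_post(author="c1", kind=Kind.COMMENT, parent="orig1",
                           attitude="query"))
    return Dataset(posts=posts)
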