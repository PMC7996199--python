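"""Core domain types and I/O for rumor-rebuttal interaction datasets.

A dataset is a flat table of posts — original microblog posts plus the
retweets and comments they received — together with manual content codes
(attitude, information, civility) and a tokenized text field.  A sentiment
lexicon holds graded sentiment words, adverb modifiers and negation words.

File formats are deliberately plain text: a delimited post table (tokens
packed into one column with a configurable intra-field separator), a
three-section lexicon file, GraphML for network export.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd

__all__ = [
    "Kind",
    "Attitude",
    "InfoCode",
    "CivilityCode",
    "Post",
    "SentimentLexicon",
    "Dataset",
    "SchemaError",
    "IntegrityError",
    "LexiconError",
    "read_posts",
    "write_posts",
    "read_lexicon",
    "write_lexicon",
    "export_graphml",
    "import_graphml",
]


class SchemaError(ValueError):
    """A post table is missing a required column or has an unparsable field."""


class IntegrityError(ValueError):
    """Referential integrity of the post table is broken."""


class LexiconError(ValueError):
    """A sentiment lexicon violates its validity constraints."""


class Kind(str, enum.Enum):
    ORIGINAL = "original"
    RETWEET = "retweet"
    COMMENT = "comment"


class Attitude(str, enum.Enum):
    AGREE = "agree"
    DISAGREE = "disagree"
    QUERY = "query"
    UNKNOWN = "unknown"


#: Attitudes that express a codeable stance (everything except ``unknown``).
CLEAR_ATTITUDES = (Attitude.AGREE, Attitude.DISAGREE, Attitude.QUERY)


class InfoCode(str, enum.Enum):
    SEEKING = "seeking"
    SHARING = "sharing"
    NONE = "none"


class CivilityCode(str, enum.Enum):
    CIVIL = "civil"
    UNCIVIL = "uncivil"


VALID_INTENSITIES = frozenset({1, 3, 5, 7, 9})

REQUIRED_COLUMNS = (
    "post_id",
    "author_id",
    "timestamp",
    "kind",
    "parent_post_id",
    "topic",
    "tokens",
    "attitude_code",
    "info_code",
    "civility_code",
)


@dataclass(slots=True)
class Post:
    """One interaction record: an original post, a retweet or a comment.

    ``parent_post_id`` is ``None`` iff the post is an original.  Original
    posts carry ``attitude_code == Attitude.AGREE`` by convention: authors
    of rebuttal posts endorse their own rebuttal.
    """

    post_id: str
    author_id: str
    timestamp: str  # ISO-8601; lexicographic order == chronological order
    kind: Kind
    parent_post_id: Optional[str]
    topic: str
    tokens: tuple[str, ...]
    attitude_code: Attitude
    info_code: InfoCode
    civility_code: CivilityCode

    def __post_init__(self) -> None:
        self.kind = Kind(self.kind)
        self.attitude_code = Attitude(self.attitude_code)
        self.info_code = InfoCode(self.info_code)
        self.civility_code = CivilityCode(self.civility_code)
        self.tokens = tuple(self.tokens)
        if self.kind is Kind.ORIGINAL:
            if self.parent_post_id is not None:
                raise IntegrityError(
                    f"original post {self.post_id!r} must not have a parent"
                )
            if self.attitude_code is not Attitude.AGREE:
                raise IntegrityError(
                    f"original post {self.post_id!r} must be coded 'agree', "
                    f"got {self.attitude_code.value!r}"
                )
        elif self.parent_post_id is None:
            raise IntegrityError(
                f"{self.kind.value} post {self.post_id!r} has no parent_post_id"
            )
        try:
            datetime.fromisoformat(self.timestamp)
        except ValueError as exc:
            raise SchemaError(
                f"post {self.post_id!r}: unparsable timestamp {self.timestamp!r}"
            ) from exc


@dataclass(frozen=True)
class SentimentLexicon:
    """Dictionary for graded sentiment scoring.

    sentiment_entries
        token -> (polarity in {+1, -1}, intensity in {1, 3, 5, 7, 9}).
    adverb_entries
        token -> modifier value in (0, 2]; values above 1 amplify, below 1
        attenuate the modified sentiment word.
    negation_words
        tokens that flip the sign of the sentiment word they modify.

    The three vocabularies must be pairwise disjoint.
    """

    sentiment_entries: Mapping[str, tuple[int, int]]
    adverb_entries: Mapping[str, float]
    negation_words: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sentiment_entries", dict(self.sentiment_entries)
        )
        object.__setattr__(self, "adverb_entries", dict(self.adverb_entries))
        object.__setattr__(
            self, "negation_words", frozenset(self.negation_words)
        )
        for token, (polarity, intensity) in self.sentiment_entries.items():
            if polarity not in (1, -1):
                raise LexiconError(
                    f"sentiment word {token!r}: polarity must be +1 or -1, "
                    f"got {polarity!r}"
                )
            if intensity not in VALID_INTENSITIES:
                raise LexiconError(
                    f"sentiment word {token!r}: intensity must be one of "
                    f"{sorted(VALID_INTENSITIES)}, got {intensity!r}"
                )
        for token, value in self.adverb_entries.items():
            if not (0.0 < float(value) <= 2.0):
                raise LexiconError(
                    f"adverb {token!r}: modifier value must lie in (0, 2], "
                    f"got {value!r}"
                )
        sent = set(self.sentiment_entries)
        adv = set(self.adverb_entries)
        neg = set(self.negation_words)
        overlap = (sent & adv) | (sent & neg) | (adv & neg)
        if overlap:
            raise LexiconError(
                "lexicon sections must be pairwise disjoint; shared tokens: "
                + ", ".join(sorted(overlap))
            )

    @property
    def positive_words(self) -> list[str]:
        return [t for t, (p, _) in self.sentiment_entries.items() if p > 0]

    @property
    def negative_words(self) -> list[str]:
        return [t for t, (p, _) in self.sentiment_entries.items() if p < 0]


@dataclass
class Dataset:
    """A validated collection of posts plus optional lexicon and provenance."""

    posts: list[Post]
    lexicon: Optional[SentimentLexicon] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for p in self.posts:
            if p.post_id in seen:
                raise IntegrityError(f"duplicate post_id {p.post_id!r}")
            seen.add(p.post_id)
        dangling = [
            p.post_id
            for p in self.posts
            if p.parent_post_id is not None and p.parent_post_id not in seen
        ]
        if dangling:
            raise IntegrityError(
                "posts with dangling parent_post_id: " + ", ".join(dangling)
            )

    def __len__(self) -> int:
        return len(self.posts)

    @property
    def by_id(self) -> dict[str, Post]:
        return {p.post_id: p for p in self.posts}

    @property
    def topics(self) -> list[str]:
        out: list[str] = []
        for p in self.posts:
            if p.topic not in out:
                out.append(p.topic)
        return out

    def of_kind(self, kind: Kind) -> list[Post]:
        kind = Kind(kind)
        return [p for p in self.posts if p.kind is kind]

    def to_frame(self, token_sep: str = "|") -> pd.DataFrame:
        rows = []
        for p in self.posts:
            for tok in p.tokens:
                if token_sep in tok:
                    raise SchemaError(
                        f"token {tok!r} contains the token separator "
                        f"{token_sep!r}; choose another separator"
                    )
            rows.append(
                {
                    "post_id": p.post_id,
                    "author_id": p.author_id,
                    "timestamp": p.timestamp,
                    "kind": p.kind.value,
                    "parent_post_id": p.parent_post_id or "",
                    "topic": p.topic,
                    "tokens": token_sep.join(p.tokens),
                    "attitude_code": p.attitude_code.value,
                    "info_code": p.info_code.value,
                    "civility_code": p.civility_code.value,
                }
            )
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def _posts_from_frame(frame: pd.DataFrame, token_sep: str) -> list[Post]:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            "post table is missing required column(s): " + ", ".join(missing)
        )
    posts = []
    for row in frame.itertuples(index=False):
        tokens = tuple(t for t in str(row.tokens).split(token_sep) if t)
        parent = str(row.parent_post_id)
        posts.append(
            Post(
                post_id=str(row.post_id),
                author_id=str(row.author_id),
                timestamp=str(row.timestamp),
                kind=Kind(str(row.kind)),
                parent_post_id=parent if parent else None,
                topic=str(row.topic),
                tokens=tokens,
                attitude_code=Attitude(str(row.attitude_code)),
                info_code=InfoCode(str(row.info_code)),
                civility_code=CivilityCode(str(row.civility_code)),
            )
        )
    return posts


def read_posts(
    path: Union[str, Path],
    delimiter: str = "\t",
    token_sep: str = "|",
) -> Dataset:
    """Read a delimited post table into a validated :class:`Dataset`.

    A first line starting with ``#`` (a provenance header written by the
    pipeline) is skipped.  Row order is preserved; it breaks timestamp ties.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        skip = 1 if first.startswith("#") else 0
    frame = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        skiprows=skip,
    )
    posts = _posts_from_frame(frame, token_sep)
    return Dataset(posts=posts, provenance={"source": str(path)})


def write_posts(
    dataset: Dataset,
    path: Union[str, Path],
    delimiter: str = "\t",
    token_sep: str = "|",
    header_comment: Optional[str] = None,
) -> None:
    """Write the post table as delimited text (inverse of :func:`read_posts`)."""
    frame = dataset.to_frame(token_sep=token_sep)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Lexicon I/O — three-section plain text:
#   [sentiment]  token  polarity(+1|-1)  intensity(1|3|5|7|9)
#   [adverbs]    token  value in (0, 2]
#   [negations]  token
# ---------------------------------------------------------------------------

_SECTIONS = ("sentiment", "adverbs", "negations")


def read_lexicon(path: Union[str, Path]) -> SentimentLexicon:
    """Parse a three-section lexicon file; all invariants are enforced."""
    sentiment: dict[str, tuple[int, int]] = {}
    adverbs: dict[str, float] = {}
    negations: set[str] = set()
    section: Optional[str] = None
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in _SECTIONS:
                raise LexiconError(
                    f"line {lineno}: unknown section {section!r}; expected "
                    f"one of {_SECTIONS}"
                )
            continue
        if section is None:
            raise LexiconError(f"line {lineno}: entry before any section header")
        parts = line.split()
        try:
            if section == "sentiment":
                token, polarity, intensity = parts
                sentiment[token] = (int(polarity), int(intensity))
            elif section == "adverbs":
                token, value = parts
                adverbs[token] = float(value)
            else:
                (token,) = parts
                negations.add(token)
        except ValueError as exc:
            raise LexiconError(
                f"line {lineno}: malformed {section} entry {line!r}"
            ) from exc
    return SentimentLexicon(
        sentiment_entries=sentiment,
        adverb_entries=adverbs,
        negation_words=frozenset(negations),
    )


def write_lexicon(lexicon: SentimentLexicon, path: Union[str, Path]) -> None:
    lines = ["[sentiment]"]
    for token, (polarity, intensity) in sorted(lexicon.sentiment_entries.items()):
        lines.append(f"{token} {polarity:+d} {intensity}")
    lines.append("[adverbs]")
    for token, value in sorted(lexicon.adverb_entries.items()):
        lines.append(f"{token} {value:g}")
    lines.append("[negations]")
    lines.extend(sorted(lexicon.negation_words))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# GraphML export (replaces interactive visualization: nodes carry attitude or
# attitude score, community id and size; edges carry weight)
# ---------------------------------------------------------------------------


def _as_graph(network) -> nx.DiGraph:
    if isinstance(network, (nx.Graph, nx.DiGraph)):
        return network
    graph = getattr(network, "graph", None)
    if isinstance(graph, (nx.Graph, nx.DiGraph)):
        return graph
    raise TypeError(f"cannot extract a graph from {type(network).__name__}")


def export_graphml(network, path: Union[str, Path]) -> None:
    """Write a user- or community-level network as GraphML.

    An empty network is written as an empty graph with a warning rather
    than raising, so batch exports do not abort on degenerate topics.
    """
    graph = _as_graph(network)
    if graph.number_of_nodes() == 0:
        warnings.warn(f"exporting empty network to {path}", stacklevel=2)
    nx.write_graphml(graph, str(path))


def import_graphml(path: Union[str, Path]) -> nx.DiGraph:
    return nx.read_graphml(str(path))
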