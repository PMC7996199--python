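"""Lexicon-based sentiment intensity scoring with adverb and negation handling.

Each sentiment word W carries a base intensity Sensibility(W) in
{1, 3, 5, 7, 9} and a polarity sign.  Adverbs contribute multiplicative
modifier values in (0, 2]; each negation word flips the sign.  The modified
intensity of one sentiment-word occurrence is

    Sensibility(Pair) = polarity * (-1)^n * (prod of adverb values) * Sensibility(W)

where n counts the negations in the word's modifier window.  The score of a
text is the plain sum of the modified intensities of its m sentiment words;
a positive sum is labelled positive, negative negative, zero neutral.

Modifier scope: adverbs and negations attach to the *next* sentiment word,
looking back to the previous sentiment word or the last sentence-final
punctuation mark, whichever is nearer.  Trailing modifiers with no
following sentiment word in the clause are discarded.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .data_model import SentimentLexicon, VALID_INTENSITIES

__all__ = [
    "SentimentLabel",
    "ScoredTerm",
    "SentimentScore",
    "CLAUSE_BOUNDARIES",
    "modified_intensity",
    "scope_modifiers",
    "score_text",
]

#: Sentence-final punctuation that closes a modifier window.
CLAUSE_BOUNDARIES = frozenset({".", "!", "?", "。", "！", "？", ";", "；"})


class SentimentLabel(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class ScoredTerm:
    """One sentiment-word occurrence with its collected modifiers."""

    token: str
    base_intensity: int
    polarity: int
    adverb_values: tuple[float, ...]
    n_negations: int

    @property
    def modified_value(self) -> float:
        return modified_intensity(
            self.base_intensity, self.polarity, self.adverb_values, self.n_negations
        )


@dataclass(frozen=True)
class SentimentScore:
    value: float
    label: SentimentLabel

    @staticmethod
    def from_value(value: float) -> "SentimentScore":
        if value > 0:
            label = SentimentLabel.POSITIVE
        elif value < 0:
            label = SentimentLabel.NEGATIVE
        else:
            label = SentimentLabel.NEUTRAL
        return SentimentScore(value=value, label=label)


def modified_intensity(
    base: int,
    polarity: int,
    adverbs: Iterable[float] = (),
    n_neg: int = 0,
) -> float:
    """Signed modified intensity of one sentiment word.

    ``polarity * (-1)**n_neg * prod(adverbs) * base``; an empty adverb
    list contributes a factor of 1.
    """
    if base not in VALID_INTENSITIES:
        raise ValueError(
            f"base intensity must be one of {sorted(VALID_INTENSITIES)}, got {base!r}"
        )
    if polarity not in (1, -1):
        raise ValueError(f"polarity must be +1 or -1, got {polarity!r}")
    if n_neg < 0:
        raise ValueError(f"negation count must be >= 0, got {n_neg}")
    product = 1.0
    for v in adverbs:
        if not (0.0 < v <= 2.0):
            raise ValueError(f"adverb value must lie in (0, 2], got {v!r}")
        product *= v
    return polarity * (-1) ** n_neg * product * base


def scope_modifiers(
    tokens: Sequence[str],
    lexicon: SentimentLexicon,
    adverb_mode: str = "all",
) -> list[ScoredTerm]:
    """Attach pending adverbs/negations to each sentiment-word occurrence.

    ``adverb_mode="all"`` multiplies every pending adverb; ``"first"``
    keeps only the adverb nearest the start of the window.
    """
    if adverb_mode not in ("all", "first"):
        raise ValueError(f"adverb_mode must be 'all' or 'first', got {adverb_mode!r}")
    terms: list[ScoredTerm] = []
    pending_adverbs: list[float] = []
    pending_negs = 0
    for tok in tokens:
        if tok in lexicon.sentiment_entries:
            polarity, intensity = lexicon.sentiment_entries[tok]
            adverbs = pending_adverbs if adverb_mode == "all" else pending_adverbs[:1]
            terms.append(
                ScoredTerm(
                    token=tok,
                    base_intensity=intensity,
                    polarity=polarity,
                    adverb_values=tuple(adverbs),
                    n_negations=pending_negs,
                )
            )
            pending_adverbs = []
            pending_negs = 0
        elif tok in lexicon.adverb_entries:
            pending_adverbs.append(lexicon.adverb_entries[tok])
        elif tok in lexicon.negation_words:
            pending_negs += 1
        elif tok in CLAUSE_BOUNDARIES:
            pending_adverbs = []
            pending_negs = 0
        # any other token is transparent to the modifier window
    return terms


def score_text(
    tokens: Sequence[str],
    lexicon: SentimentLexicon,
    adverb_mode: str = "all",
) -> SentimentScore:
    """Score one tokenized text: sum of modified intensities, then label."""
    terms = scope_modifiers(tokens, lexicon, adverb_mode=adverb_mode)
    value = math.fsum(t.modified_value for t in terms)
    return SentimentScore.from_value(value)
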