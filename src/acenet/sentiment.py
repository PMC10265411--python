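"""Threshold-based sentiment classification and per-user sentiment fractions.

The numeric scorer (text -> s in [-1, 1]) is pluggable; this module only owns
the thresholds (negative iff s <= -0.05, positive iff s >= 0.05, neutral in
between) and the per-user summary.
"""

from __future__ import annotations

import enum
from fractions import Fraction
from typing import Callable, Iterable, Sequence

__all__ = [
    "NEGATIVE_MAX",
    "POSITIVE_MIN",
    "Sentiment",
    "SentimentScorer",
    "LexiconScorer",
    "classify_sentiment",
    "sentiment_profile",
]

NEGATIVE_MAX = -0.05  # inclusive upper bound for negative
POSITIVE_MIN = 0.05  # inclusive lower bound for positive

#: Any callable mapping raw text to a score in [-1, 1].
SentimentScorer = Callable[[str], float]


class Sentiment(str, enum.Enum):
    NEGATIVE = "negative"
    NEUTRAL = "neutral"
    POSITIVE = "positive"


def classify_sentiment(s: float) -> Sentiment:
    """Map a score in [-1, 1] onto the three sentiment classes."""
    if not -1.0 <= s <= 1.0:
        raise ValueError(f"sentiment score outside [-1, 1]: {s}")
    if s <= NEGATIVE_MAX:
        return Sentiment.NEGATIVE
    if s >= POSITIVE_MIN:
        return Sentiment.POSITIVE
    return Sentiment.NEUTRAL


def sentiment_profile(
    scores: Sequence[float],
) -> tuple[Fraction, Fraction, Fraction]:
    """Percentages (positive, negative, neutral) over a user's eligible texts.

    Returned as exact rationals on the 0-100 scale so the three always sum
    to exactly 100; callers may cast to float for display.
    """
    if not scores:
        raise ValueError("sentiment profile undefined for an empty score list")
    counts = {s: 0 for s in Sentiment}
    for s in scores:
        counts[classify_sentiment(s)] += 1
    n = len(scores)
    return (
        Fraction(100 * counts[Sentiment.POSITIVE], n),
        Fraction(100 * counts[Sentiment.NEGATIVE], n),
        Fraction(100 * counts[Sentiment.NEUTRAL], n),
    )


class LexiconScorer:
    """Tiny deterministic word-count scorer used as the default plugin in tests.

    Score = (positive hits - negative hits) / max(1, total tokens), clipped
    to [-1, 1].  This is a stand-in for an external rule-based scorer, not a
    reimplementation of one.
    """

    def __init__(
        self,
        positive_words: Iterable[str] = ("love", "great", "happy", "good", "wonderful"),
        negative_words: Iterable[str] = ("hate", "awful", "sad", "bad", "terrible"),
    ):
        self.positive = frozenset(positive_words)
        self.negative = frozenset(negative_words)

    def __call__(self, text: str) -> float:
        tokens = text.lower().split()
        if not tokens:
            return 0.0
        raw = sum(t in self.positive for t in tokens) - sum(
            t in self.negative for t in tokens
        )
        return max(-1.0, min(1.0, raw / len(tokens)))
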