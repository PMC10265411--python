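"""Per-user aggregation of mention scores into an alignment index and category.

A user's alignment index is the top-decile value of their eligible-document
mention scores; it is defined only when the user has at least
``MIN_ELIGIBLE`` eligible documents (more than 5 words after cleaning).
Users with index >= 0.5 are ACE; users whose every eligible score is < 0.3
are non-ACE; everything in between is indeterminate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from acenet.classifier import ScorerModel
from acenet.text_preprocess import DEFAULT_MIN_WORDS, CleanedDocument

__all__ = [
    "MIN_ELIGIBLE",
    "ACE_THRESHOLD",
    "NON_ACE_CEILING",
    "Category",
    "UserProfile",
    "alignment_index",
    "categorize",
    "score_users",
]

MIN_ELIGIBLE = 30
ACE_THRESHOLD = 0.5  # inclusive: alpha >= 0.5 -> ACE
NON_ACE_CEILING = 0.3  # exclusive: all scores < 0.3 -> non-ACE


class Category(str, enum.Enum):
    ACE = "ACE"
    NON_ACE = "NON_ACE"
    INDETERMINATE = "INDETERMINATE"
    INSUFFICIENT_DATA = "INSUFFICIENT_DATA"


def alignment_index(
    scores: Sequence[float],
    *,
    min_eligible: int = MIN_ELIGIBLE,
    method: str = "nearest_rank",
) -> float | None:
    """Top-decile alignment index of a score list, or None below the evidence floor.

    ``method="nearest_rank"`` (default) returns the ceil(0.9 n)-th smallest
    score — the nearest-rank 90th percentile.  ``method="top_fraction"``
    returns the smallest value of the top ceil(0.1 n) scores (the
    ceil(0.1 n)-th largest), an alternative reading of "top 10% value".
    """
    n = len(scores)
    if n < min_eligible:
        return None
    ordered = sorted(scores)
    if method == "nearest_rank":
        k = math.ceil(0.9 * n)
    elif method == "top_fraction":
        k = n - math.ceil(0.1 * n) + 1
    else:
        raise ValueError(f"unknown percentile method: {method!r}")
    return float(ordered[k - 1])


@dataclass
class UserProfile:
    """A user's eligible mention scores with derived alignment index and category."""

    user_id: str
    eligible_scores: list[float] = field(default_factory=list)
    min_eligible: int = MIN_ELIGIBLE

    @property
    def n_eligible(self) -> int:
        return len(self.eligible_scores)

    @property
    def alpha(self) -> float | None:
        return alignment_index(self.eligible_scores, min_eligible=self.min_eligible)

    @property
    def category(self) -> Category:
        return categorize(self)


def categorize(profile: UserProfile) -> Category:
    """Assign exactly one category from the alignment index and score ceiling.

    Both the ACE and non-ACE labels require the >= ``min_eligible`` evidence
    floor; accounts below it are INSUFFICIENT_DATA regardless of scores.
    """
    if profile.n_eligible < profile.min_eligible:
        return Category.INSUFFICIENT_DATA
    alpha = profile.alpha
    if alpha is not None and alpha >= ACE_THRESHOLD:
        return Category.ACE
    if max(profile.eligible_scores) < NON_ACE_CEILING:
        return Category.NON_ACE
    return Category.INDETERMINATE


def score_users(
    model: ScorerModel,
    documents_by_user: Mapping[str, Iterable[CleanedDocument]],
    *,
    min_words: int = DEFAULT_MIN_WORDS,
    min_eligible: int = MIN_ELIGIBLE,
) -> list[UserProfile]:
    """Score each user's eligible documents and build their profile.

    Eligibility is word_count > ``min_words`` after cleaning; ineligible
    documents are never scored.
    """
    profiles = []
    for user_id, docs in documents_by_user.items():
        eligible = [d for d in docs if d.word_count > min_words]
        if eligible:
            scores = list(map(float, model.score_documents(eligible)))
        else:
            scores = []
        profiles.append(
            UserProfile(
                user_id=user_id, eligible_scores=scores, min_eligible=min_eligible
            )
        )
    return profiles
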