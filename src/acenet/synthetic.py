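"""Synthetic inputs for every pipeline stage, with planted parameters.

Three generators:

* :func:`generate_corpus` — a two-class token corpus with separable
  class-specific signal vocabularies (mixing rate ``epsilon``) and document
  lengths in [6, 45], for classifier training tests.
* :func:`generate_user_streams` — per-user mention-score lists with planted
  group membership (high-score mass for ACE users, a < 0.3 ceiling for
  non-ACE users) that the categorizer must recover.
* :func:`generate_ego_network` — directed egocentric networks with planted
  follow-back probability ``p_back``, triangle-closure probability
  ``p_tri``, group-assortative neighbor draws (homophily ``h``), and
  per-group alignment-index distributions, for parameter-recovery tests.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from acenet.classifier import LabeledCorpus
from acenet.ego_network import SAMPLE_CAP, DirectedEgoNetwork
from acenet.text_preprocess import CleanedDocument

__all__ = [
    "CorpusSpec",
    "UserStreamSpec",
    "EgoNetSpec",
    "UserStream",
    "GeneratedEgoNet",
    "generate_corpus",
    "generate_user_streams",
    "generate_ego_network",
    "generate_ego_networks",
]

MAX_TOTAL_DEGREE = 7089  # truncation ceiling for heavy-tailed degree draws

#: Per-group alignment-index distributions for generated neighbors:
#: normal(mean, sd) truncated to [0, 1].
DEFAULT_ALPHA_PARAMS: dict[str, tuple[float, float]] = {
    "ACE": (0.81, 0.12),
    "NON_ACE_1": (0.44, 0.09),
    "NON_ACE_2": (0.36, 0.13),
}


# ---------------------------------------------------------------------------
# labeled corpus
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusSpec:
    n_pos: int = 1000
    n_neg: int = 1000
    vocab_size: int = 200
    n_signal: int = 30  # per-class signal token count
    epsilon: float = 0.1  # probability a signal slot uses the other class's tokens
    signal_rate: float = 0.4  # fraction of slots that carry class signal
    length_range: tuple[int, int] = (6, 45)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (5 < lo <= hi <= 45):
            raise ValueError("length_range must lie within (5, 45]")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5) for separability")
        if 2 * self.n_signal >= self.vocab_size:
            raise ValueError("vocab must be larger than the two signal sets")


def generate_corpus(spec: CorpusSpec) -> LabeledCorpus:
    """Draw a labeled two-class corpus token-wise from class distributions."""
    rng = np.random.default_rng(spec.seed)
    pos_signal = [f"w{i}" for i in range(spec.n_signal)]
    neg_signal = [f"w{i}" for i in range(spec.n_signal, 2 * spec.n_signal)]
    shared = [f"w{i}" for i in range(2 * spec.n_signal, spec.vocab_size)]
    docs, labels = [], []
    lo, hi = spec.length_range
    for i in range(spec.n_pos + spec.n_neg):
        label = 1 if i < spec.n_pos else 0
        own, other = (pos_signal, neg_signal) if label else (neg_signal, pos_signal)
        length = int(rng.integers(lo, hi + 1))
        tokens = []
        for _ in range(length):
            if rng.random() < spec.signal_rate:
                pool = other if rng.random() < spec.epsilon else own
            else:
                pool = shared
            tokens.append(pool[rng.integers(len(pool))])
        docs.append(CleanedDocument(doc_id=f"d{i}", tokens=tuple(tokens)))
        labels.append(label)
    return LabeledCorpus(documents=docs, labels=labels)


# ---------------------------------------------------------------------------
# per-user score streams
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UserStreamSpec:
    """Planted score streams per group.

    ACE users get a planted fraction ``ace_high_frac`` of scores drawn from
    ``ace_high_range`` (all >= 0.5); the planted count is forced to exceed
    10% of the stream so the nearest-rank top-decile index is >= 0.5 by
    construction.  Non-ACE users draw every score below 0.3.
    """

    n_users: Mapping[str, int] = field(
        default_factory=lambda: {"ACE": 100, "NON_ACE_1": 100, "NON_ACE_2": 100}
    )
    n_texts_range: tuple[int, int] = (30, 60)
    ace_high_frac: float = 0.15
    ace_high_range: tuple[float, float] = (0.55, 0.95)
    ace_low_range: tuple[float, float] = (0.0, 0.45)
    nonace1_range: tuple[float, float] = (0.02, 0.28)
    nonace2_range: tuple[float, float] = (0.0, 0.25)

    def __post_init__(self) -> None:
        if self.n_texts_range[0] < 30:
            raise ValueError("every user needs at least 30 eligible texts")
        if self.ace_high_range[0] < 0.5:
            raise ValueError("planted high scores must be >= 0.5")
        if max(self.nonace1_range[1], self.nonace2_range[1]) >= 0.3:
            raise ValueError("non-ACE scores must stay below 0.3")


@dataclass(frozen=True)
class UserStream:
    user_id: str
    group: str
    scores: tuple[float, ...]


def generate_user_streams(spec: UserStreamSpec, seed: int = 0) -> list[UserStream]:
    """Generate score streams whose planted group the categorizer recovers."""
    rng = np.random.default_rng(seed)
    streams = []
    for group, count in spec.n_users.items():
        for i in range(count):
            n = int(rng.integers(spec.n_texts_range[0], spec.n_texts_range[1] + 1))
            if group == "ACE":
                # strictly more than 10% high scores, so the ceil(0.9 n)-th
                # smallest is guaranteed >= 0.5
                n_high = max(
                    math.floor(0.1 * n) + 1, round(spec.ace_high_frac * n)
                )
                scores = np.concatenate(
                    [
                        rng.uniform(*spec.ace_high_range, size=n_high),
                        rng.uniform(*spec.ace_low_range, size=n - n_high),
                    ]
                )
                rng.shuffle(scores)
            elif group == "NON_ACE_1":
                scores = rng.uniform(*spec.nonace1_range, size=n)
            elif group == "NON_ACE_2":
                scores = rng.uniform(*spec.nonace2_range, size=n)
            else:
                raise ValueError(f"unknown group: {group!r}")
            streams.append(
                UserStream(
                    user_id=f"{group.lower()}_u{i}",
                    group=group,
                    scores=tuple(float(s) for s in scores),
                )
            )
    return streams


# ---------------------------------------------------------------------------
# egocentric networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EgoNetSpec:
    """Planted-parameter generator spec for directed egocentric networks.

    ``p_back`` maps each group to its follow-back probability (applied
    independently per neighbor on both sides).  ``h`` is the probability a
    neighbor shares the root's group; ``h=None`` draws neighbor groups
    uniformly from the pooled mix (the group-blind null).
    """

    n_roots: Mapping[str, int] = field(
        default_factory=lambda: {"ACE": 50, "NON_ACE_1": 50, "NON_ACE_2": 50}
    )
    p_back: Mapping[str, float] = field(
        default_factory=lambda: {"ACE": 0.4, "NON_ACE_1": 0.3, "NON_ACE_2": 0.2}
    )
    p_tri: float = 0.2
    h: float | None = None
    alpha_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ALPHA_PARAMS)
    )
    p_alpha_observed: float = 0.7  # chance a neighbor has a computable index
    degree_mu: float = math.log(200.0)  # lognormal parameters for k_in, k_out
    degree_sigma: float = 1.2
    fixed_degrees: tuple[int, int] | None = None  # force (k_in, k_out)
    cap: int = SAMPLE_CAP

    def __post_init__(self) -> None:
        for p in (*self.p_back.values(), self.p_tri, self.p_alpha_observed):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.h is not None and not 0.0 <= self.h <= 1.0:
            raise ValueError("homophily h must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratedEgoNet:
    group: str
    network: DirectedEgoNetwork
    alpha_map: dict
    neighbor_groups: dict


def _draw_degree(spec: EgoNetSpec, rng: np.random.Generator) -> int:
    k = int(math.floor(rng.lognormal(spec.degree_mu, spec.degree_sigma)))
    return min(k, MAX_TOTAL_DEGREE)


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float) -> float:
    # rejection sampling; acceptance is high for all shipped parameter sets
    while True:
        x = rng.normal(mean, sd)
        if 0.0 <= x <= 1.0:
            return float(x)


def _neighbor_group(
    spec: EgoNetSpec, root_group: str, groups: Sequence[str], rng
) -> str:
    if spec.h is None:
        return groups[rng.integers(len(groups))]
    if rng.random() < spec.h:
        return root_group
    others = [g for g in groups if g != root_group]
    return others[rng.integers(len(others))]


def _close_pairs(recip: Sequence, spec: EgoNetSpec, rng, edges: set) -> None:
    for v1, v2 in combinations(recip, 2):
        if rng.random() < spec.p_tri:
            if rng.random() < 0.5:
                edges.add((v1, v2))
                edges.add((v2, v1))
            else:
                edges.add((v1, v2) if rng.random() < 0.5 else (v2, v1))


def generate_ego_network(
    spec: EgoNetSpec,
    root_group: str,
    rng: np.random.Generator | int = 0,
    root_id: str = "root",
) -> GeneratedEgoNet:
    """One root's sampled network with planted reciprocity/clustering/homophily."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    groups = list(spec.alpha_params.keys())
    p_back = spec.p_back[root_group]

    k_in, k_out = spec.fixed_degrees or (_draw_degree(spec, rng), _draw_degree(spec, rng))
    m1, m2 = min(k_in, spec.cap), min(k_out, spec.cap)
    followers = [f"{root_id}_fr{i}" for i in range(m1)]
    followees = [f"{root_id}_fe{i}" for i in range(m2)]

    edges: set = set()
    edges.update((f, root_id) for f in followers)
    edges.update((root_id, g) for g in followees)
    recip_followers = [f for f in followers if rng.random() < p_back]
    edges.update((root_id, f) for f in recip_followers)
    recip_followees = [g for g in followees if rng.random() < p_back]
    edges.update((g, root_id) for g in recip_followees)

    _close_pairs(recip_followers, spec, rng, edges)
    _close_pairs(recip_followees, spec, rng, edges)

    alpha_map: dict = {}
    neighbor_groups: dict = {}
    for node in followers + followees:
        g = _neighbor_group(spec, root_group, groups, rng)
        neighbor_groups[node] = g
        if rng.random() < spec.p_alpha_observed:
            alpha_map[node] = _truncnorm01(rng, *spec.alpha_params[g])

    # reciprocated followees are real (unsampled) followers of the root, and
    # vice versa: declared totals must cover them so that edge-list exports
    # stay self-consistent
    k_in = max(k_in, m1 + len(recip_followees))
    k_out = max(k_out, m2 + len(recip_followers))
    net = DirectedEgoNetwork(
        root=root_id,
        followers=frozenset(followers),
        followees=frozenset(followees),
        edges=frozenset(edges),
        k_in=k_in,
        k_out=k_out,
    )
    return GeneratedEgoNet(
        group=root_group, network=net, alpha_map=alpha_map,
        neighbor_groups=neighbor_groups,
    )


def generate_ego_networks(spec: EgoNetSpec, seed: int = 0) -> list[GeneratedEgoNet]:
    """All roots of all groups, reproducibly, with per-root unique ids."""
    rng = np.random.default_rng(seed)
    out = []
    for group, count in spec.n_roots.items():
        for i in range(count):
            out.append(
                generate_ego_network(
                    spec, group, rng, root_id=f"{group.lower()}_r{i}"
                )
            )
    return out
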