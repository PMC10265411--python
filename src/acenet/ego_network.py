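"""Sampled directed egocentric follow networks and their indexes.

A network is rooted at one user; edges point follower -> followee.  The
module computes, per root: reciprocity r1 (over sampled followers) and r2
(over sampled followees), local clustering coefficients restricted to
reciprocal-neighbor pairs in strict (both edges between the pair) and weak
(at least one edge) versions, homophily averages of neighbor alignment
indexes, the reciprocal-vs-nonreciprocal follower split, and degree survival
curves.

"Undefined" is a value here, not an exception: indexes gated by the < 5
sampled-neighbor guard (or with no pairs / no scored neighbors) are None and
are expected to propagate as missing values into group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MIN_NEIGHBORS",
    "SAMPLE_CAP",
    "DirectedEgoNetwork",
    "EgoNetworkIndexes",
    "SurvivalCurve",
    "sample_neighbors",
    "reciprocal_neighbors_from_followers",
    "reciprocal_neighbors_from_followees",
    "reciprocity_r1",
    "reciprocity_r2",
    "clustering",
    "homophily_avg",
    "reciprocal_split_avg",
    "compute_indexes",
    "survival_probability",
]

NodeId = Hashable

SAMPLE_CAP = 100  # at most this many followers/followees are sampled per root
MIN_NEIGHBORS = 5  # indexes undefined when the sampled side has fewer


@dataclass(frozen=True)
class DirectedEgoNetwork:
    """A root user with sampled neighbors and the directed edges among them.

    ``edges`` contains pairs (a, b) meaning "a follows b" over
    {root} | followers | followees.  ``k_in``/``k_out`` are the root's total
    follower/followee counts before sampling (default: the sampled counts).
    """

    root: NodeId
    followers: frozenset
    followees: frozenset
    edges: frozenset
    k_in: int = -1
    k_out: int = -1

    def __post_init__(self) -> None:
        object.__setattr__(self, "followers", frozenset(self.followers))
        object.__setattr__(self, "followees", frozenset(self.followees))
        object.__setattr__(self, "edges", frozenset(self.edges))
        if self.k_in < 0:
            object.__setattr__(self, "k_in", len(self.followers))
        if self.k_out < 0:
            object.__setattr__(self, "k_out", len(self.followees))
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
        for f in self.followers:
            if (f, self.root) not in self.edges:
                raise ValueError(f"follower {f!r} lacks edge to root")
        for g in self.followees:
            if (self.root, g) not in self.edges:
                raise ValueError(f"followee {g!r} lacks edge from root")
        if len(self.followers) > self.k_in or len(self.followees) > self.k_out:
            raise ValueError("sampled neighbors exceed declared totals")

    @property
    def m1(self) -> int:
        return len(self.followers)

    @property
    def m2(self) -> int:
        return len(self.followees)


def sample_neighbors(
    full_followers: Sequence[NodeId],
    full_followees: Sequence[NodeId],
    cap: int = SAMPLE_CAP,
    seed: int | np.random.Generator = 0,
) -> tuple[list[NodeId], list[NodeId]]:
    """Sample up to ``cap`` followers and followees uniformly without replacement.

    All neighbors are retained when a side has at most ``cap`` of them.
    Reproducible under a fixed seed.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    def pick(pool: Sequence[NodeId]) -> list[NodeId]:
        if len(pool) <= cap:
            return list(pool)
        idx = rng.choice(len(pool), size=cap, replace=False)
        return [pool[i] for i in idx]

    return pick(full_followers), pick(full_followees)


def reciprocal_neighbors_from_followers(net: DirectedEgoNetwork) -> set:
    """Sampled followers whom the root follows back."""
    return {f for f in net.followers if (net.root, f) in net.edges}


def reciprocal_neighbors_from_followees(net: DirectedEgoNetwork) -> set:
    """Sampled followees who follow the root back."""
    return {g for g in net.followees if (g, net.root) in net.edges}


def reciprocity_r1(net: DirectedEgoNetwork) -> float | None:
    """Fraction of sampled followers that are reciprocal; None when m1 < 5."""
    if net.m1 < MIN_NEIGHBORS:
        return None
    return len(reciprocal_neighbors_from_followers(net)) / net.m1


def reciprocity_r2(net: DirectedEgoNetwork) -> float | None:
    """Fraction of sampled followees that are reciprocal; None when m2 < 5."""
    if net.m2 < MIN_NEIGHBORS:
        return None
    return len(reciprocal_neighbors_from_followees(net)) / net.m2


def clustering(
    net: DirectedEgoNetwork,
    neighbor_source: str = "followers",
    strength: str = "strict",
) -> float | None:
    """Local clustering over unordered pairs of reciprocal neighbors.

    ``strict`` counts a pair when both directed edges between the two
    neighbors exist; ``weak`` when at least one does.  Undefined (None) when
    the chosen side has < 5 sampled neighbors or < 2 reciprocal neighbors.
    """
    if neighbor_source == "followers":
        if net.m1 < MIN_NEIGHBORS:
            return None
        recip = reciprocal_neighbors_from_followers(net)
    elif neighbor_source == "followees":
        if net.m2 < MIN_NEIGHBORS:
            return None
        recip = reciprocal_neighbors_from_followees(net)
    else:
        raise ValueError(f"unknown neighbor_source: {neighbor_source!r}")
    if strength not in ("strict", "weak"):
        raise ValueError(f"unknown strength: {strength!r}")
    if len(recip) < 2:
        return None
    pairs = list(combinations(sorted(recip, key=repr), 2))
    hits = 0
    for v1, v2 in pairs:
        fwd = (v1, v2) in net.edges
        bwd = (v2, v1) in net.edges
        hits += (fwd and bwd) if strength == "strict" else (fwd or bwd)
    return hits / len(pairs)


def _mean_alpha(nodes: Iterable[NodeId], alpha_map: Mapping) -> float | None:
    vals = [alpha_map[v] for v in nodes if v in alpha_map]
    return float(np.mean(vals)) if vals else None


def homophily_avg(
    net: DirectedEgoNetwork, alpha_map: Mapping, side: str = "follower"
) -> float | None:
    """Mean alignment index over side-neighbors with a computable index.

    The root's own index is never included.  None when no neighbor on that
    side appears in ``alpha_map``.
    """
    if side == "follower":
        nodes = net.followers
    elif side == "followee":
        nodes = net.followees
    else:
        raise ValueError(f"unknown side: {side!r}")
    return _mean_alpha(nodes, alpha_map)


def reciprocal_split_avg(
    net: DirectedEgoNetwork, alpha_map: Mapping
) -> tuple[float | None, float | None]:
    """Mean alignment index over (reciprocal, nonreciprocal) sampled followers."""
    recip = reciprocal_neighbors_from_followers(net)
    nonrecip = net.followers - recip
    return _mean_alpha(recip, alpha_map), _mean_alpha(nonrecip, alpha_map)


@dataclass(frozen=True)
class EgoNetworkIndexes:
    """All per-root indexes; None marks an undefined (guarded) value."""

    root: NodeId
    m1: int
    m2: int
    k_in: int
    k_out: int
    r1: float | None
    r2: float | None
    c1: float | None
    c1p: float | None
    c2: float | None
    c2p: float | None
    avg_alpha_follower: float | None
    avg_alpha_followee: float | None
    avg_alpha_reciprocal: float | None
    avg_alpha_nonreciprocal: float | None

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "m1": self.m1,
            "m2": self.m2,
            "k_in": self.k_in,
            "k_out": self.k_out,
            "r1": self.r1,
            "r2": self.r2,
            "c1": self.c1,
            "c1p": self.c1p,
            "c2": self.c2,
            "c2p": self.c2p,
            "avg_alpha_follower": self.avg_alpha_follower,
            "avg_alpha_followee": self.avg_alpha_followee,
            "avg_alpha_reciprocal": self.avg_alpha_reciprocal,
            "avg_alpha_nonreciprocal": self.avg_alpha_nonreciprocal,
        }


def compute_indexes(
    net: DirectedEgoNetwork, alpha_map: Mapping | None = None
) -> EgoNetworkIndexes:
    """Compute every index for one root; missing alpha_map leaves averages None."""
    alpha_map = alpha_map or {}
    recip_avg, nonrecip_avg = reciprocal_split_avg(net, alpha_map)
    return EgoNetworkIndexes(
        root=net.root,
        m1=net.m1,
        m2=net.m2,
        k_in=net.k_in,
        k_out=net.k_out,
        r1=reciprocity_r1(net),
        r2=reciprocity_r2(net),
        c1=clustering(net, "followers", "strict"),
        c1p=clustering(net, "followers", "weak"),
        c2=clustering(net, "followees", "strict"),
        c2p=clustering(net, "followees", "weak"),
        avg_alpha_follower=homophily_avg(net, alpha_map, "follower"),
        avg_alpha_followee=homophily_avg(net, alpha_map, "followee"),
        avg_alpha_reciprocal=recip_avg,
        avg_alpha_nonreciprocal=nonrecip_avg,
    )


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical survival function of non-negative integer values.

    ``curve(k)`` is the fraction of values >= k: a nonincreasing,
    right-continuous step function with curve(0) == 1.
    """

    sorted_values: tuple[int, ...]

    def __call__(self, k) -> float | np.ndarray:
        n = len(self.sorted_values)
        arr = np.asarray(self.sorted_values)
        k = np.asarray(k)
        out = (n - np.searchsorted(arr, k, side="left")) / n
        return float(out) if out.ndim == 0 else out

    @property
    def support(self) -> tuple[int, ...]:
        """Distinct observed values, ascending: the step locations."""
        return tuple(sorted(set(self.sorted_values)))


def survival_probability(values: Sequence[int]) -> SurvivalCurve:
    """Survival function k -> fraction of values at least k."""
    if len(values) == 0:
        raise ValueError("survival probability undefined for an empty list")
    if any(v < 0 for v in values):
        raise ValueError("values must be non-negative")
    return SurvivalCurve(sorted_values=tuple(sorted(int(v) for v in values)))
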