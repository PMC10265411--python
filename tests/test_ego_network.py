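from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acenet.ego_network import (
    DirectedEgoNetwork,
    clustering,
    compute_indexes,
    homophily_avg,
    reciprocal_neighbors_from_followers,
    reciprocal_split_avg,
    reciprocity_r1,
    reciprocity_r2,
    sample_neighbors,
    survival_probability,
)
from conftest import random_ego_network


# ---------------------------------------------------------------------------
# independent enumeration oracles
# ---------------------------------------------------------------------------


def r_oracle(net, side):
    neighbors = net.followers if side == 1 else net.followees
    if len(neighbors) < 5:
        return None
    count = 0
    for v in neighbors:
        if (v, net.root) in net.edges and (net.root, v) in net.edges:
            count += 1
    return count / len(neighbors)


def clustering_oracle(net, source, strength):
    side_set = net.followers if source == "followers" else net.followees
    if len(side_set) < 5:
        return None
    recip = [
        v
        for v in side_set
        if (v, net.root) in net.edges and (net.root, v) in net.edges
    ]
    pairs = list(combinations(sorted(recip), 2))
    if not pairs:
        return None
    hit = 0
    for v1, v2 in pairs:
        both = (v1, v2) in net.edges and (v2, v1) in net.edges
        either = (v1, v2) in net.edges or (v2, v1) in net.edges
        hit += both if strength == "strict" else either
    return hit / len(pairs)


def homophily_oracle(net, alpha_map, side):
    nodes = net.followers if side == "follower" else net.followees
    vals = [alpha_map[v] for v in nodes if v in alpha_map]
    return sum(vals) / len(vals) if vals else None


def build_net(root, followers, followees, extra_edges=()):
    edges = {(f, root) for f in followers} | {(root, g) for g in followees}
    edges |= set(extra_edges)
    return DirectedEgoNetwork(
        root=root, followers=followers, followees=followees, edges=edges
    )


class TestNetworkInvariants:
    def test_follower_edge_required(self):
        with pytest.raises(ValueError):
            DirectedEgoNetwork(
                root="u", followers={"f"}, followees=set(), edges=set()
            )

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            DirectedEgoNetwork(
                root="u", followers=set(), followees=set(), edges={("u", "u")}
            )

    def test_sampled_counts_cannot_exceed_totals(self):
        with pytest.raises(ValueError):
            DirectedEgoNetwork(
                root="u",
                followers={"a", "b"},
                followees=set(),
                edges={("a", "u"), ("b", "u")},
                k_in=1,
                k_out=0,
            )


class TestSampleNeighbors:
    def test_all_retained_below_cap(self):
        followers = [f"f{i}" for i in range(50)]
        out, _ = sample_neighbors(followers, [], cap=100, seed=0)
        assert sorted(out) == sorted(followers)

    def test_cap_binding(self):
        followers = [f"f{i}" for i in range(500)]
        out, _ = sample_neighbors(followers, [], cap=100, seed=0)
        assert len(out) == 100 and len(set(out)) == 100

    def test_reproducible(self):
        pool = [f"n{i}" for i in range(300)]
        assert sample_neighbors(pool, pool, seed=42) == sample_neighbors(
            pool, pool, seed=42
        )

    def test_invalid_cap(self):
        with pytest.raises(ValueError):
            sample_neighbors([], [], cap=0)


class TestReciprocity:
    def test_worked_example_r1_r2(self, fig_reciprocity_net):
        net = fig_reciprocity_net
        assert net.m1 == 5 and net.m2 == 6
        assert len(reciprocal_neighbors_from_followers(net)) == 2
        assert reciprocity_r1(net) == pytest.approx(2 / 5)
        assert reciprocity_r2(net) == pytest.approx(1 / 3)

    def test_r1_guard_below_five_followers(self):
        net = build_net("u", {"a", "b", "c", "d"}, set())
        assert reciprocity_r1(net) is None

    def test_r2_guard_below_five_followees(self):
        net = build_net("u", set(), {"a", "b", "c"})
        assert reciprocity_r2(net) is None

    def test_all_reciprocated(self):
        followers = {f"f{i}" for i in range(10)}
        net = build_net("u", followers, followers)
        assert reciprocity_r1(net) == 1.0

    def test_no_outgoing_edges(self):
        net = build_net("u", {f"f{i}" for i in range(6)}, set())
        assert reciprocal_neighbors_from_followers(net) == set()
        assert reciprocity_r1(net) == 0.0

    def test_full_sampling_agrees_across_sides(self):
        # when caps do not bind, the reciprocal set is the same whether
        # derived from followers or followees
        rng = np.random.default_rng(7)
        for _ in range(200):
            nodes = [f"v{i}" for i in range(int(rng.integers(1, 12)))]
            mutual = {v for v in nodes if rng.random() < 0.5}
            only_in = {v for v in nodes if v not in mutual and rng.random() < 0.5}
            only_out = set(nodes) - mutual - only_in
            followers = mutual | only_in
            followees = mutual | only_out
            net = build_net(
                "u",
                followers,
                followees,
                {("u", v) for v in mutual} | {(v, "u") for v in mutual},
            )
            from acenet.ego_network import reciprocal_neighbors_from_followees

            assert (
                reciprocal_neighbors_from_followers(net)
                == reciprocal_neighbors_from_followees(net)
                == mutual
            )


class TestClustering:
    def make_recip_net(self, n_recip, extra_followers=2, inter_edges=()):
        recip = {f"r{i}" for i in range(n_recip)}
        others = {f"o{i}" for i in range(extra_followers)}
        followers = recip | others
        edges = {(f, "u") for f in followers} | {("u", r) for r in recip}
        edges |= set(inter_edges)
        return DirectedEgoNetwork(
            root="u", followers=followers, followees=recip, edges=edges
        )

    def test_fully_mutual_triangle(self):
        inter = {("r0", "r1"), ("r1", "r0"), ("r0", "r2"), ("r2", "r0"),
                 ("r1", "r2"), ("r2", "r1")}
        net = self.make_recip_net(3, inter_edges=inter)
        assert clustering(net, "followers", "strict") == 1.0
        assert clustering(net, "followers", "weak") == 1.0

    def test_one_way_edge_counts_only_for_weak(self):
        net = self.make_recip_net(2, extra_followers=3, inter_edges={("r0", "r1")})
        assert clustering(net, "followers", "strict") == 0.0
        assert clustering(net, "followers", "weak") == 1.0

    def test_guard_fewer_than_two_reciprocal(self):
        net = self.make_recip_net(1, extra_followers=5)
        assert clustering(net, "followers", "strict") is None

    def test_guard_small_side(self):
        net = self.make_recip_net(2, extra_followers=1)  # m1 = 4 < 5
        assert clustering(net, "followers", "strict") is None

    def test_invalid_arguments(self):
        net = self.make_recip_net(2, extra_followers=3)
        with pytest.raises(ValueError):
            clustering(net, "everyone")
        with pytest.raises(ValueError):
            clustering(net, "followers", "medium")

    def test_random_instance_matches_pair_enumeration(self):
        rng = np.random.default_rng(13)
        recip = [f"r{i}" for i in range(10)]
        inter = {
            (a, b) for a in recip for b in recip if a != b and rng.random() < 0.4
        }
        net = self.make_recip_net(10, extra_followers=0, inter_edges=inter)
        for strength in ("strict", "weak"):
            assert clustering(net, "followers", strength) == pytest.approx(
                clustering_oracle(net, "followers", strength)
            )


class TestHomophily:
    def test_worked_follower_average(self, fig_homophily_net):
        net, alpha = fig_homophily_net
        assert homophily_avg(net, alpha, "follower") == pytest.approx(0.6)

    def test_worked_followee_average(self, fig_homophily_net):
        net, alpha = fig_homophily_net
        assert homophily_avg(net, alpha, "followee") == pytest.approx(0.5)

    def test_worked_reciprocal_split(self, fig_homophily_net):
        net, alpha = fig_homophily_net
        recip_avg, nonrecip_avg = reciprocal_split_avg(net, alpha)
        assert recip_avg == pytest.approx(0.65)
        assert nonrecip_avg == pytest.approx(0.5)

    def test_undefined_when_no_computable_alpha(self, fig_homophily_net):
        net, _ = fig_homophily_net
        assert homophily_avg(net, {}, "follower") is None

    def test_root_alpha_never_included(self, fig_homophily_net):
        net, alpha = fig_homophily_net
        with_root = dict(alpha, u=1.0)
        assert homophily_avg(net, with_root, "follower") == pytest.approx(0.6)

    def test_all_reciprocated_nonreciprocal_undefined(self):
        followers = {f"f{i}" for i in range(5)}
        net = build_net("u", followers, followers)
        alpha = {f: 0.4 for f in followers}
        recip_avg, nonrecip_avg = reciprocal_split_avg(net, alpha)
        assert recip_avg == pytest.approx(0.4)
        assert nonrecip_avg is None


class TestOracleEquivalence:
    """All indexes vs exhaustive enumeration on random networks (<= 15 nodes)."""

    def test_indexes_match_oracles(self):
        rng = np.random.default_rng(99)
        for _ in range(500):
            net = random_ego_network(rng)
            alpha = {
                v: float(rng.random())
                for v in (net.followers | net.followees)
                if rng.random() < 0.7
            }
            ix = compute_indexes(net, alpha)
            assert ix.r1 == pytest.approx(r_oracle(net, 1))
            assert ix.r2 == pytest.approx(r_oracle(net, 2))
            for got, src, strength in (
                (ix.c1, "followers", "strict"),
                (ix.c1p, "followers", "weak"),
                (ix.c2, "followees", "strict"),
                (ix.c2p, "followees", "weak"),
            ):
                assert got == pytest.approx(clustering_oracle(net, src, strength))
            assert ix.avg_alpha_follower == pytest.approx(
                homophily_oracle(net, alpha, "follower")
            )
            assert ix.avg_alpha_followee == pytest.approx(
                homophily_oracle(net, alpha, "followee")
            )

    def test_strict_never_exceeds_weak(self):
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(2000):
            net = random_ego_network(rng, max_nodes=10)
            for src in ("followers", "followees"):
                strict = clustering(net, src, "strict")
                weak = clustering(net, src, "weak")
                if strict is not None:
                    assert 0.0 <= strict <= weak <= 1.0
                    checked += 1
        assert checked > 100


class TestSurvivalProbability:
    def test_fraction_at_least_k(self):
        curve = survival_probability([1, 2, 3])
        assert curve(2) == pytest.approx(2 / 3)

    def test_at_zero(self):
        assert survival_probability([1, 2, 3])(0) == 1.0

    def test_beyond_max(self):
        assert survival_probability([1, 2, 3])(4) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            survival_probability([])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            survival_probability([3, -1])

    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=50))
    @settings(max_examples=100)
    def test_nonincreasing_step_function(self, values):
        curve = survival_probability(values)
        grid = np.arange(0, max(values) + 2)
        out = curve(grid)
        assert np.all(np.diff(out) <= 1e-12)
        assert out[0] == 1.0

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=30))
    def test_right_continuous_steps(self, values):
        curve = survival_probability(values)
        for k in curve.support:
            # value at the step location equals the value just after it
            assert curve(k) == pytest.approx((np.asarray(values) >= k).mean())
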