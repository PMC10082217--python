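"""Prefix-Pearson scoring: profiles, f values, ranking, estimator API."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from sourceloc import (
    DelayModel,
    ObserverRecord,
    PearsonSourceLocator,
    all_pairs_hop_distance,
    f_score,
    make_fixture_network,
    observer_order,
    pearson_coefficient,
    prefix_pearson_profile,
    rank_candidates,
    score_all_nodes,
    simulate_diffusion,
)
from sourceloc.locate import ScoreTable
from .conftest import random_connected_network


class TestPearsonCoefficient:
    def test_exact_affine(self):
        assert pearson_coefficient([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_coefficient([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_zero_variance_is_undefined(self):
        assert pearson_coefficient([1, 1, 1], [1, 2, 3]) is None
        assert pearson_coefficient([1, 2, 3], [5, 5, 5]) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_coefficient([1, 2], [1, 2, 3])

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=10),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bounded_in_unit_interval(self, xs, seed):
        ys = np.random.default_rng(seed).normal(size=len(xs))
        rho = pearson_coefficient(xs, ys)
        assert rho is None or -1.0 <= rho <= 1.0


class TestObserverOrder:
    def test_sorts_by_distance(self):
        net = make_fixture_network("path7")
        obs = ObserverRecord(["3", "1", "2"], [0.0, 0.0, 0.0])
        dist = all_pairs_hop_distance(net)
        # distances from candidate "0": 3, 1, 2 -> order (1st=\"1\", 2nd=\"2\", 3rd=\"3\")
        assert list(observer_order("0", obs, dist)) == [1, 2, 0]

    def test_equal_distances_keep_record_order(self):
        net = make_fixture_network("path7")
        obs = ObserverRecord(["2", "4", "3"], [0.0, 0.0, 0.0])
        dist = all_pairs_hop_distance(net)
        # candidate "3": distances 1, 1, 0 -> "3" first, then stable record order
        assert list(observer_order("3", obs, dist)) == [2, 0, 1]

    def test_sorted_distances_non_decreasing(self, rng):
        for _ in range(10):
            net = random_connected_network(rng)
            obs_nodes = list(rng.choice(net.nodes, size=3, replace=False))
            obs = ObserverRecord(obs_nodes, rng.normal(size=3))
            dist = all_pairs_hop_distance(net)
            for cand in net.nodes:
                d = np.array([dist[cand, o] for o in obs.observers])
                assert np.all(np.diff(d[observer_order(cand, obs, dist)]) >= 0)


class TestPrefixProfile:
    def test_perfectly_correlated_times(self):
        net = make_fixture_network("path7")
        obs = ObserverRecord(["1", "2", "3"], [2.0, 4.0, 6.0])
        dist = all_pairs_hop_distance(net)
        # from candidate "0" sorted distances (1,2,3) align with times (2,4,6)
        np.testing.assert_allclose(
            prefix_pearson_profile("0", obs, dist), [1.0, 1.0]
        )
        assert f_score("0", obs, dist) == pytest.approx(2.0)

    def test_constant_times_give_neutral_profile(self):
        net = make_fixture_network("path7")
        obs = ObserverRecord(["1", "2", "3"], [5.0, 5.0, 5.0])
        dist = all_pairs_hop_distance(net)
        np.testing.assert_array_equal(
            prefix_pearson_profile("0", obs, dist), [0.0, 0.0]
        )

    def test_reversed_times_give_negative_extreme(self):
        net = make_fixture_network("path7")
        obs = ObserverRecord(["1", "2", "3"], [6.0, 4.0, 2.0])
        dist = all_pairs_hop_distance(net)
        assert f_score("0", obs, dist) == pytest.approx(-2.0)

    def test_noiseless_source_profile_entries(self):
        # times are exactly affine in distance, so every prefix with varying
        # distances contributes 1; all-equal-distance prefixes contribute 0
        net = make_fixture_network("locatable10")
        source = "3"
        res = simulate_diffusion(net, [source], 0.0, DelayModel(2.0, 0.0), seed=0)
        observers = [v for v in net.nodes if v != source]
        obs = ObserverRecord(observers, res.times_for(observers))
        dist = all_pairs_hop_distance(net)
        d_sorted = np.sort([dist[source, o] for o in observers])
        expected = [
            1.0 if len(set(d_sorted[:h])) > 1 else 0.0
            for h in range(2, obs.r + 1)
        ]
        np.testing.assert_allclose(
            prefix_pearson_profile(source, obs, dist), expected, atol=1e-12
        )


class TestScoreAllNodes:
    def test_noiseless_source_attains_strict_maximum(self):
        net = make_fixture_network("locatable10")
        for source in ("0", "3", "9"):
            res = simulate_diffusion(net, [source], 0.0, DelayModel(2.0, 0.0), seed=0)
            obs = ObserverRecord(net.nodes, res.times_for(net.nodes))
            table = score_all_nodes(net, obs)
            assert table.f[source] == pytest.approx(obs.r - 1)
            others = [table.f[v] for v in net.nodes if v != source]
            assert max(others) < table.f[source] - 1e-9

    def test_observer_permutation_invariance_without_distance_ties(self, rng):
        net = random_connected_network(rng)
        obs_nodes = list(rng.choice(net.nodes, size=4, replace=False))
        times = list(rng.normal(size=4))
        dist = all_pairs_hop_distance(net)
        perm = list(rng.permutation(4))
        t1 = score_all_nodes(net, ObserverRecord(obs_nodes, times), dist=dist)
        t2 = score_all_nodes(
            net,
            ObserverRecord([obs_nodes[i] for i in perm], [times[i] for i in perm]),
            dist=dist,
        )
        for cand in net.nodes:
            d = [dist[cand, o] for o in obs_nodes]
            if len(set(d)) == len(d):  # tie-break convention only affects ties
                assert t1.f[cand] == pytest.approx(t2.f[cand], abs=1e-9)

    def test_f_bounded_by_r_minus_one(self, rng):
        for _ in range(5):
            net = random_connected_network(rng)
            obs_nodes = list(rng.choice(net.nodes, size=3, replace=False))
            table = score_all_nodes(net, ObserverRecord(obs_nodes, rng.normal(size=3)))
            assert all(abs(f) <= 2 + 1e-9 for f in table.f.values())

    @given(st.floats(-50, 50), st.floats(0.1, 20))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_affine_time_invariance(self, shift, scale):
        net = make_fixture_network("locatable10")
        rng = np.random.default_rng(99)
        obs_nodes = ["0", "4", "7", "9"]
        times = rng.normal(2.0, 1.0, size=4)
        t1 = score_all_nodes(net, ObserverRecord(obs_nodes, times))
        t2 = score_all_nodes(net, ObserverRecord(obs_nodes, shift + scale * times))
        for v in net.nodes:
            assert t1.f[v] == pytest.approx(t2.f[v], abs=1e-8)

    def test_observers_must_exist(self, path3):
        with pytest.raises(ValueError, match="unknown observer"):
            score_all_nodes(path3, ObserverRecord(["a", "b", "z"], [0, 1, 2]))


class TestObserverRecord:
    def test_validation(self):
        with pytest.raises(ValueError):
            ObserverRecord(["a", "b"], [0.0, 1.0])  # r < 3
        with pytest.raises(ValueError):
            ObserverRecord(["a", "a", "b"], [0, 1, 2])
        with pytest.raises(ValueError):
            ObserverRecord(["a", "b", "c"], [0.0, np.inf, 1.0])


class TestRankCandidates:
    def test_descending_with_identifier_ties(self):
        table = ScoreTable(f={"a": 3.0, "b": 1.0, "c": 2.0}, r=4)
        assert rank_candidates(table) == ["a", "c", "b"]

    def test_all_equal_flags_ties(self):
        table = ScoreTable(f={"b": 1.0, "a": 1.0, "c": 1.0}, r=4)
        ranking, ties = rank_candidates(table, return_ties=True)
        assert ranking == ["a", "b", "c"] and ties

    def test_sign_flip_reverses_order(self, rng):
        f = {f"v{i}": float(x) for i, x in enumerate(rng.normal(size=8))}
        fwd = rank_candidates(ScoreTable(f=f, r=9))
        rev = rank_candidates(ScoreTable(f={k: -v for k, v in f.items()}, r=9))
        assert fwd == rev[::-1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates(ScoreTable(f={}, r=3))


class TestPearsonSourceLocator:
    def test_fit_predict_score_roundtrip(self):
        net = make_fixture_network("locatable10")
        res = simulate_diffusion(net, ["6"], 0.0, DelayModel(2.0, 0.0), seed=0)
        loc = PearsonSourceLocator(net).fit(
            ObserverRecord(net.nodes, res.times_for(net.nodes))
        )
        assert loc.predict(1) == ("6",)
        assert loc.score(["6"]) == 1.0
        assert loc.decision_function(["6"])[0] == pytest.approx(9.0)

    def test_sklearn_param_interface(self):
        net = make_fixture_network("path7")
        loc = PearsonSourceLocator(net, keep_profile=True)
        params = loc.get_params()
        assert params["keep_profile"] is True
        cloned = clone(loc)
        assert cloned.get_params()["network"] == net

    def test_unfitted_access_raises(self):
        with pytest.raises(RuntimeError):
            PearsonSourceLocator(make_fixture_network("path7")).predict(1)
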