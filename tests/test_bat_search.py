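"""The discrete swarm: objective, initialization, per-iteration operators
and the full alignment loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from batalign.bat_search import (AlignResult, Bat, BatParams, accept_step,
                                 align, binarize_frequency, check_alignment,
                                 conserved_edges, draw_frequency,
                                 global_search, greedy_init_position,
                                 init_velocity, local_search, step_bat,
                                 update_velocity)
from batalign.io_formats import Network
from batalign.metrics import node_correctness, s3

from conftest import random_alignment, random_network


def brute_conserved(target_of, net1, net2):
    """Edge-loop oracle: test each source edge's image for membership."""
    e2 = {frozenset(e) for e in net2.edge_array.tolist()}
    return sum(1 for u, v in net1.edge_array
               if frozenset((int(target_of[u]), int(target_of[v]))) in e2)


class TestConservedEdges:
    def test_triangle_identity(self, triangle):
        assert conserved_edges(np.arange(3), triangle, triangle) == 3

    def test_path_to_independent_set(self):
        path = Network(["a", "b", "c"], [(0, 1), (1, 2)])
        # targets 0,1,2 pairwise non-adjacent in a 4-node graph
        tgt = Network(["w", "x", "y", "z"], [(0, 3), (1, 3), (2, 3)])
        assert conserved_edges(np.array([0, 1, 2]), path, tgt) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_edge_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1 = random_network(10, 0.3, rng)
        n2 = random_network(12, 0.3, rng)
        aln = random_alignment(10, 12, rng)
        assert conserved_edges(aln, n1, n2) == brute_conserved(aln, n1, n2)


class TestGreedyInit:
    def test_identity_similarity(self, rng):
        aln = greedy_init_position(np.eye(5), rng)
        assert np.array_equal(aln, np.arange(5))

    def test_all_zero_gives_random_injective(self, rng):
        aln = greedy_init_position(np.zeros((6, 9)), rng)
        check_alignment(aln, 6, 9)

    def test_matches_argmax_deletion_oracle(self, rng):
        S = rng.uniform(0.1, 1.0, (4, 5))
        assert len(np.unique(S)) == S.size  # distinct entries, no ties
        work = S.copy()
        expected = np.full(4, -1)
        for _ in range(4):
            i, j = np.unravel_index(np.argmax(work), work.shape)
            expected[i] = j
            work[i, :] = -1
            work[:, j] = -1
        aln = greedy_init_position(S, np.random.default_rng(0))
        assert np.array_equal(aln, expected)

    def test_source_larger_than_target_error(self, rng):
        with pytest.raises(ValueError):
            greedy_init_position(np.zeros((5, 3)), rng)


class TestInitVelocity:
    def test_identity_self_alignment(self, rng):
        net = Network(["a", "b", "c", "d"], [(0, 1), (1, 2)])  # d isolated
        fly = init_velocity(np.arange(4), net, net)
        assert fly.tolist() == [0, 0, 0, 1]

    def test_edgeless_source_all_fly(self, rng):
        n1 = Network(["a", "b"], [])
        n2 = random_network(4, 0.8, rng)
        assert init_velocity(np.array([0, 1]), n1, n2).tolist() == [1, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_conserved_endpoint_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1 = random_network(12, 0.3, rng)
        n2 = random_network(15, 0.3, rng)
        aln = random_alignment(12, 15, rng)
        e2 = {frozenset(e) for e in n2.edge_array.tolist()}
        frozen = set()
        for u, v in n1.edge_array:
            if frozenset((int(aln[u]), int(aln[v]))) in e2:
                frozen.update((int(u), int(v)))
        fly = init_velocity(aln, n1, n2)
        assert {i for i in range(12) if fly[i] == 0} == frozen


class TestFrequency:
    def test_degenerate_band(self, rng):
        p = BatParams(f_min=1.0, f_max=1.0)
        assert all(draw_frequency(p, rng) == 1.0 for _ in range(10))

    def test_uniform_mean(self):
        p = BatParams()
        rng = np.random.default_rng(7)
        draws = [draw_frequency(p, rng) for _ in range(100_000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.01)

    def test_seed_reproducible(self):
        p = BatParams()
        a = [draw_frequency(p, np.random.default_rng(3)) for _ in range(1)]
        b = [draw_frequency(p, np.random.default_rng(3)) for _ in range(1)]
        assert a == b

    @pytest.mark.parametrize("f,expect", [(0.7, 1), (0.3, 0), (0.5, 0)])
    def test_binarize_threshold(self, f, expect):
        assert binarize_frequency(f, BatParams()) == expect


class TestUpdateVelocity:
    def _bat(self, pos, vel):
        return Bat(position=np.array(pos), velocity=np.array(vel, dtype=np.int8),
                   loudness=1.0, rate=0.0, objective=0)

    def test_position_equal_best_keeps_velocity(self):
        bat = self._bat([0, 1, 2], [1, 0, 1])
        got = update_velocity(bat, np.array([0, 1, 2]), 0)
        assert got.tolist() == [1, 0, 1]

    def test_frozen_disjoint_stays_frozen(self):
        bat = self._bat([0, 1, 2], [0, 0, 0])
        got = update_velocity(bat, np.array([3, 4, 5]), 1)
        assert got.tolist() == [0, 0, 0]

    def test_flying_disjoint_takes_frequency(self):
        bat = self._bat([0, 1, 2], [1, 1, 1])
        assert update_velocity(bat, np.array([3, 4, 5]), 1).tolist() == [1, 1, 1]
        assert update_velocity(bat, np.array([3, 4, 5]), 0).tolist() == [0, 0, 0]


class TestSearchMoves:
    def test_global_all_frozen_unchanged(self, rng):
        pos = random_alignment(5, 8, rng)
        out = global_search(pos, np.zeros(5, dtype=np.int8), 8, rng)
        assert np.array_equal(out, pos)

    def test_global_all_fly_equal_sizes_is_permutation(self, rng):
        pos = np.arange(6)
        out = global_search(pos, np.ones(6, dtype=np.int8), 6, rng)
        check_alignment(out, 6, 6)

    def test_global_mixed_properties_bulk(self):
        """Frozen dims unchanged, new targets drawn outside the pinned
        set, injectivity preserved — 1000 random cases."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n2 = int(rng.integers(4, 15))
            n1 = int(rng.integers(2, n2 + 1))
            pos = random_alignment(n1, n2, rng)
            vel = rng.integers(0, 2, size=n1).astype(np.int8)
            out = global_search(pos, vel, n2, rng)
            check_alignment(out, n1, n2)
            frozen = vel == 0
            assert np.array_equal(out[frozen], pos[frozen])
            pinned = set(pos[frozen].tolist())
            assert not pinned & set(out[~frozen].tolist())

    def test_local_conserves_target_multiset_bulk(self):
        rng = np.random.default_rng(43)
        for _ in range(1000):
            n2 = int(rng.integers(4, 15))
            n1 = int(rng.integers(2, n2 + 1))
            pos = random_alignment(n1, n2, rng)
            vel = rng.integers(0, 2, size=n1).astype(np.int8)
            out = local_search(pos, vel, rng)
            check_alignment(out, n1, n2)
            frozen = vel == 0
            assert np.array_equal(out[frozen], pos[frozen])
            assert sorted(out.tolist()) == sorted(pos.tolist())

    def test_local_singleton_unchanged(self, rng):
        pos = random_alignment(4, 6, rng)
        vel = np.array([0, 0, 1, 0], dtype=np.int8)
        assert np.array_equal(local_search(pos, vel, rng), pos)


class TestAcceptStep:
    def _setup(self, rng):
        n1 = random_network(8, 0.4, rng)
        n2 = random_network(10, 0.4, rng)
        pos = random_alignment(8, 10, rng)
        bat = Bat(position=pos, velocity=init_velocity(pos, n1, n2),
                  loudness=1.0, rate=0.0,
                  objective=conserved_edges(pos, n1, n2))
        return n1, n2, bat

    def test_non_improving_candidate_rejected(self, rng):
        n1, n2, bat = self._setup(rng)
        out = accept_step(bat, bat.position.copy(), bat.objective, 3,
                          BatParams(), rng, n1, n2)
        assert out is bat

    def test_loudness_decays_by_theta(self, rng):
        n1, n2, bat = self._setup(rng)
        cand = bat.position.copy()
        out = accept_step(bat, cand, bat.objective + 1, 1,
                          BatParams(theta=0.9), rng, n1, n2)
        assert out.loudness == pytest.approx(0.9)

    def test_rate_growth_limits(self, rng):
        n1, n2, bat = self._setup(rng)
        params = BatParams(gamma=0.9, rate0=0.5)
        at0 = accept_step(bat, bat.position.copy(), bat.objective + 1, 0,
                          params, rng, n1, n2)
        assert at0.rate == pytest.approx(0.0)
        late = accept_step(bat, bat.position.copy(), bat.objective + 1, 500,
                           params, rng, n1, n2)
        assert late.rate == pytest.approx(params.rate0, abs=1e-9)


class TestStepBat:
    def test_fixed_point_at_best_with_frozen_velocity(self, rng):
        n1 = random_network(8, 0.5, rng)
        pos = np.arange(8)
        bat = Bat(position=pos, velocity=np.zeros(8, dtype=np.int8),
                  loudness=1.0, rate=0.0,
                  objective=conserved_edges(pos, n1, n1))
        out = step_bat(bat, pos.copy(), 1, n1, n1, BatParams(), rng)
        assert np.array_equal(out.position, pos)
        assert out.objective == bat.objective

    def test_objective_monotone_over_steps(self):
        """A bat's cached objective never decreases across 500 accepted or
        rejected steps."""
        rng = np.random.default_rng(11)
        n1 = random_network(15, 0.3, rng)
        n2 = random_network(18, 0.3, rng)
        pos = random_alignment(15, 18, rng)
        bat = Bat(position=pos, velocity=init_velocity(pos, n1, n2),
                  loudness=1.0, rate=0.0,
                  objective=conserved_edges(pos, n1, n2))
        best = random_alignment(15, 18, rng)
        params = BatParams()
        prev = bat.objective
        for t in range(1, 501):
            bat = step_bat(bat, best, t, n1, n2, params, rng)
            assert bat.objective >= prev
            assert bat.objective == conserved_edges(bat.position, n1, n2)
            prev = bat.objective


class TestAlign:
    def _permuted_pair(self, n, p, seed):
        rng = np.random.default_rng(seed)
        net1 = random_network(n, p, rng)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        net2 = Network([f"t{i}" for i in range(n)],
                       [(inv[u], inv[v]) for u, v in net1.edge_array])
        S = np.zeros((n, n))
        S[np.arange(n), inv] = 1.0
        return net1, net2, inv.astype(np.int64), S

    def test_noiseless_recovery(self):
        """Graph vs relabeled copy with indicator similarity: the greedy
        seed is already perfect and patience stops the run."""
        net1, net2, truth, S = self._permuted_pair(30, 0.15, seed=5)
        params = BatParams(seed=1)
        res = align(net1, net2, S, params)
        assert node_correctness(res.alignment, truth) == 1.0
        assert res.objective == net1.m
        assert s3(res.alignment, net1, net2) == 1.0
        assert res.n_iter == params.patience  # stagnation fired

    def test_zero_iters_returns_greedy_seed(self):
        net1, net2, truth, S = self._permuted_pair(12, 0.3, seed=6)
        res = align(net1, net2, S, BatParams(pop_size=1, max_iters=0, seed=0))
        assert np.array_equal(res.alignment, truth)
        assert res.trace == [net1.m]

    def test_same_seed_same_run(self, rng):
        net1 = random_network(20, 0.2, rng)
        net2 = random_network(24, 0.2, rng, prefix="t")
        S = np.random.default_rng(9).uniform(0, 1, (20, 24))
        params = BatParams(max_iters=40, patience=40, seed=77)
        a = align(net1, net2, S, params)
        b = align(net1, net2, S, params)
        assert np.array_equal(a.alignment, b.alignment)
        assert a.trace == b.trace and a.n_iter == b.n_iter

    def test_trace_non_decreasing(self, rng):
        net1 = random_network(20, 0.25, rng)
        net2 = random_network(25, 0.25, rng, prefix="t")
        S = np.random.default_rng(3).uniform(0, 1, (20, 25))
        res = align(net1, net2, S, BatParams(max_iters=60, seed=4))
        assert all(b >= a for a, b in zip(res.trace, res.trace[1:]))
        assert isinstance(res, AlignResult)

    def test_size_errors(self, rng):
        small = random_network(3, 0.5, rng)
        big = random_network(5, 0.5, rng, prefix="t")
        with pytest.raises(ValueError):
            align(big, small, np.zeros((5, 3)), BatParams())
        with pytest.raises(ValueError):
            align(Network([], []), small, np.zeros((0, 3)), BatParams())


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(min_value=2, max_value=10),
       st.integers(min_value=0, max_value=8),
       st.integers(min_value=0, max_value=2**31 - 1))
def test_every_operator_preserves_injectivity(n1, extra, seed):
    """greedy seeding, global search and local search all return valid
    injective alignments for arbitrary sizes and velocities."""
    rng = np.random.default_rng(seed)
    n2 = n1 + extra
    S = rng.uniform(0, 1, (n1, n2)) * (rng.uniform(size=(n1, n2)) < 0.5)
    pos = greedy_init_position(S, rng)
    check_alignment(pos, n1, n2)
    vel = rng.integers(0, 2, size=n1).astype(np.int8)
    check_alignment(global_search(pos, vel, n2, rng), n1, n2)
    check_alignment(local_search(pos, vel, rng), n1, n2)
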