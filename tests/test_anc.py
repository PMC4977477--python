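import math

import numpy as np
import pytest

from ancfold.anc import (AttemptRecord, BanditState, ConnectionMethod, History,
                         connect_node_global, connect_node_local,
                         cost_adjusted_probability, replay_history, reward,
                         sample_method, selection_probability_no_cost,
                         update_weights)
from ancfold.fixtures import (make_two_region_bench, run_localization_experiment,
                              run_two_arm_bench)


class ExpWeightOracle:
    """Independent straight transcription of the selection equations, kept
    deliberately naive (scalar loops, explicit running extrema)."""

    def __init__(self, m, gamma, alpha):
        self.m, self.gamma, self.alpha = m, gamma, alpha
        self.w = [1.0] * m
        self.min_y = math.inf
        self.max_y = -math.inf
        self.costs = [[] for _ in range(m)]

    def p_star(self):
        s = sum(self.w)
        return [(1 - self.gamma) * wi / s + self.gamma / self.m
                for wi in self.w]

    def p_cost(self):
        ps = self.p_star()
        avg = [sum(c) / len(c) if c else 1.0 for c in self.costs]
        ratios = [p / a for p, a in zip(ps, avg)]
        z = sum(ratios)
        return [r / z for r in ratios]

    def observe(self, i, success, y, cost):
        if success and math.isfinite(y):
            self.min_y = min(self.min_y, y)
            self.max_y = max(self.max_y, y)
            if self.max_y == self.min_y:
                x = 1.0
            else:
                x = self.alpha + (1 - self.alpha) * (
                    1 - (y - self.min_y) / (self.max_y - self.min_y))
        else:
            x = 0.0
        if x > 0:
            x_adj = x / self.p_star()[i]
            self.w[i] *= math.exp(self.gamma * x_adj / self.m)
        self.costs[i].append(cost)
        return x


def random_stream(state_ids, steps, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(steps):
        i = int(rng.integers(len(state_ids)))
        success = bool(rng.random() < 0.7)
        y = float(rng.uniform(0.1, 5.0)) if success else math.inf
        cost = float(rng.integers(1, 30))
        out.append((i, success, y, cost))
    return out


class TestSelectionEquations:
    def test_uniform_weights_give_uniform_probabilities(self):
        for gamma in (0.05, 0.3, 1.0):
            st = BanditState(method_ids=("a", "b", "c"), gamma=gamma)
            assert np.allclose(selection_probability_no_cost(st), 1 / 3)

    def test_gamma_one_ignores_weights(self):
        st = BanditState(method_ids=("a", "b"), gamma=1.0)
        st.weights = np.array([100.0, 1.0])
        assert np.allclose(selection_probability_no_cost(st), 0.5)

    def test_hand_value_two_arms(self):
        # w=(3,1), gamma -> 0: probabilities approach the relative weights
        st = BanditState(method_ids=("a", "b"), gamma=1e-12)
        st.weights = np.array([3.0, 1.0])
        assert np.allclose(selection_probability_no_cost(st), [0.75, 0.25],
                           atol=1e-9)

    def test_exploration_floor(self):
        st = BanditState(method_ids=("a", "b", "c"), gamma=0.3)
        st.weights = np.array([1e9, 1.0, 1.0])
        p = selection_probability_no_cost(st)
        assert np.all(p >= 0.3 / 3 - 1e-15)


class TestReward:
    def _state(self, lo, hi, alpha=0.5):
        st = BanditState(method_ids=("a", "b"), alpha=alpha)
        st.min_y, st.max_y = lo, hi
        return st

    def test_extremes_and_degenerate(self):
        st = self._state(1.0, 3.0)
        assert reward(1.0, st) == 1.0          # best edge seen
        assert reward(3.0, st) == 0.5          # worst edge seen -> alpha
        assert reward(2.0, st) == 0.75
        degenerate = self._state(2.0, 2.0)
        assert reward(2.0, degenerate) == 1.0  # lone observation convention

    def test_range_is_alpha_to_one(self):
        st = self._state(0.5, 7.0, alpha=0.2)
        for y in np.linspace(0.5, 7.0, 17):
            assert 0.2 <= reward(float(y), st) <= 1.0


class TestUpdateWeights:
    def test_zero_reward_keeps_all_weights(self):
        st = BanditState(method_ids=("a", "b"))
        before = st.weights.copy()
        update_weights(st, "a", 0.0)
        assert np.array_equal(st.weights, before)

    def test_exponential_factor_hand_value(self):
        # m=2, gamma=0.5, adjusted reward x* = 2  =>  factor e^{0.5}
        st = BanditState(method_ids=("a", "b"), gamma=0.5)
        p = selection_probability_no_cost(st)[0]
        x = 2.0 * p  # so that x / p* == 2
        update_weights(st, "a", x)
        assert st.weights[0] == pytest.approx(math.exp(0.5))
        assert st.weights[1] == 1.0

    def test_repeated_rewards_push_probability_to_ceiling(self):
        st = BanditState(method_ids=("a", "b"), gamma=0.2)
        prev = selection_probability_no_cost(st)[0]
        for _ in range(60):
            st.observe("a", True, 1.0, 1.0)
            cur = selection_probability_no_cost(st)[0]
            assert cur >= prev - 1e-12
            prev = cur
        ceiling = (1 - 0.2) + 0.2 / 2
        assert prev <= ceiling + 1e-12
        assert prev == pytest.approx(ceiling, abs=1e-3)


class TestCostAdjustment:
    def test_equal_costs_reduce_to_p_star(self):
        st = BanditState(method_ids=("a", "b", "c"))
        st.weights = np.array([5.0, 2.0, 1.0])
        for mid in st.method_ids:
            st.cost_totals[st.index(mid)] = 6.0
            st.cost_counts[st.index(mid)] = 2.0
        assert np.allclose(cost_adjusted_probability(st),
                           selection_probability_no_cost(st))

    def test_hand_value(self):
        # p* = (0.5, 0.5), costs (1, 2)  =>  p = (2/3, 1/3)
        st = BanditState(method_ids=("a", "b"))
        st.cost_totals[:] = (3.0, 6.0)
        st.cost_counts[:] = (3.0, 3.0)
        assert np.allclose(cost_adjusted_probability(st), [2 / 3, 1 / 3])

    def test_unseen_method_costs_one(self):
        st = BanditState(method_ids=("a", "b"))
        st.cost_totals[0], st.cost_counts[0] = 4.0, 2.0
        assert np.allclose(st.average_costs(), [2.0, 1.0])


class TestOracleEquivalence:
    def test_200_step_stream_matches_straight_transcription(self):
        """Weights and both probability vectors agree with an independently
        coded transcription to 1e-12 relative over a random stream."""
        ids = ("a", "b", "c")
        st = BanditState(method_ids=ids, gamma=0.1, alpha=0.5)
        oracle = ExpWeightOracle(3, 0.1, 0.5)
        for i, success, y, cost in random_stream(ids, 200, seed=13):
            st.observe(ids[i], success, y, cost)
            oracle.observe(i, success, y, cost)
            np.testing.assert_allclose(st.weights, oracle.w, rtol=1e-12)
            np.testing.assert_allclose(selection_probability_no_cost(st),
                                       oracle.p_star(), rtol=1e-12)
            np.testing.assert_allclose(cost_adjusted_probability(st),
                                       oracle.p_cost(), rtol=1e-12)

    def test_probability_conservation_long_stream(self):
        ids = ("a", "b", "c", "d")
        st = BanditState(method_ids=ids, gamma=0.15, alpha=0.4)
        for i, success, y, cost in random_stream(ids, 2000, seed=17):
            st.observe(ids[i], success, y, cost)
            p_star = selection_probability_no_cost(st)
            p = cost_adjusted_probability(st)
            assert abs(p_star.sum() - 1.0) < 1e-9
            assert abs(p.sum() - 1.0) < 1e-9
            assert np.all(p_star >= 0.15 / 4 - 1e-12)


class TestReplayAndDrivers:
    def test_cold_start_is_uniform(self):
        bench = make_two_region_bench(0)
        history = History()
        counts = {"cm_A": 0, "cm_B": 0}
        rng = np.random.default_rng(0)
        state = replay_history([], ("cm_A", "cm_B"))
        for _ in range(4000):
            counts[sample_method(state, bench.methods, rng).id] += 1
        assert counts["cm_A"] / 4000 == pytest.approx(0.5, abs=0.03)

    def test_replay_is_deterministic(self):
        bench = make_two_region_bench(3)
        history = History()
        rng = np.random.default_rng(5)
        q0 = bench.make_query(0, rng, "q0")
        connect_node_local(q0, bench.methods, history, rng, bench.executor())
        q1 = bench.make_query(1, rng, "q1")
        picks = set()
        for _ in range(5):
            r = connect_node_local(q1, bench.methods, History(),
                                   np.random.default_rng(9), bench.executor())
            picks.add(r.method_id)
        assert len(picks) == 1  # same history + seed -> same selection

    def test_locally_successful_method_is_favoured(self):
        """Records where cm_B succeeds near the query and cm_A succeeds far
        away: replayed neighborhood learning prefers cm_B."""
        history = History()
        near, far = np.zeros(4), np.full(4, 120.0)
        step = 0
        for _ in range(30):
            step += 1
            history.append(AttemptRecord("n", "cm_B", 0.0, 1.0, step, True,
                                         1.0, near))
            step += 1
            history.append(AttemptRecord("f", "cm_A", 0.0, 1.0, step, True,
                                         1.0, far))
            step += 1
            history.append(AttemptRecord("n2", "cm_A", 0.0, 1.0, step, False,
                                         math.inf, near))
        state = replay_history(
            [r for r in history.records if np.allclose(r.node_torsions, near)],
            ("cm_A", "cm_B"))
        p = cost_adjusted_probability(state)
        assert p[1] > 0.5  # cm_B clearly above uniform

    def test_single_method_always_selected(self):
        bench = make_two_region_bench(0)
        only = [bench.methods[0]]
        state = BanditState(method_ids=("cm_A",))
        rng = np.random.default_rng(2)
        history = History()
        q = bench.make_query(0, rng, "q")
        res = connect_node_global(q, only, state, history, rng,
                                  bench.executor())
        assert res.method_id == "cm_A"

    def test_global_follows_majority_even_in_minority_region(self):
        """With most of the history from the cm_A-favoured region, global
        selection keeps picking cm_A for minority-region queries."""
        bench = make_two_region_bench(1)
        rng = np.random.default_rng(1)
        state = BanditState(method_ids=("cm_A", "cm_B"))
        history = History()
        executor = bench.executor()
        for t in range(60):  # burn-in dominated by region 0 (cm_A territory)
            q = bench.make_query(0, rng, f"b{t}")
            connect_node_global(q, bench.methods, state, history, rng, executor)
        picks_a = 0
        trials = 200
        for t in range(trials):
            p = cost_adjusted_probability(state)
            picks_a += p[0] > 0.5
        assert picks_a / trials > 0.5


class TestBenchmarks:
    def test_two_arm_bench_prefers_better_arm(self):
        freqs = [run_two_arm_bench(seed=s, steps=300) for s in range(5)]
        assert np.mean(freqs) > 0.6

    def test_localization_beats_global_on_paired_seeds(self):
        wins = 0
        for s in range(6):
            local, global_ = run_localization_experiment(seed=50 + s,
                                                         n_queries=80,
                                                         warmup=30)
            wins += local > global_
        assert wins >= 5
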